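"""BNF-coded prescribing comparison between clusters.

Cleans records lacking chapter/section information (the chapter-99 path),
builds items-per-registered-patient monthly series per cluster at total,
chapter or section level, ranks chapters by between-cluster RMSE and runs
per-section Welch t-tests with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MISSING_CHAPTER = 99


@dataclass
class MonthlySeries:
    """Items per registered patient per month for one cluster at one BNF level."""

    label: str
    level: tuple | None  # None = all chapters, (chapter,) or (chapter, section)
    months: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.months) != len(self.values):
            raise ValueError("months and values length mismatch")
        periods = [pd.Period(m, freq="M") for m in self.months]
        for prev, cur in zip(periods, periods[1:]):
            if cur != prev + 1:
                raise ValueError("series months must be strictly increasing and contiguous")
        if not np.isfinite(self.values).all():
            raise ValueError("series values must be finite")


def clean_bnf(records: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Drop records without BNF chapter/section info (assigned chapter 99).

    Returns the retained records (integer chapter/section dtypes) and the
    excluded fraction of rows.
    """
    if records.empty:
        return records.copy(), 0.0
    chapter = pd.to_numeric(records["bnf_chapter"], errors="coerce")
    section = pd.to_numeric(records["bnf_section"], errors="coerce")
    bad = chapter.isna() | section.isna() | (chapter == MISSING_CHAPTER)
    fraction = float(bad.mean())
    retained = records.loc[~bad].copy()
    retained["bnf_chapter"] = chapter[~bad].astype(int)
    retained["bnf_section"] = section[~bad].astype(int)
    logger.info("clean_bnf: excluded %d of %d rows (%.4f%%)",
                int(bad.sum()), len(records), 100 * fraction)
    return retained, fraction


def _common_months(records: pd.DataFrame, sizes: pd.DataFrame) -> list[str]:
    months = sorted(set(records["year_month"]) & set(sizes["year_month"]))
    if not months:
        raise ValueError("records and sizes share no months")
    periods = [pd.Period(m, freq="M") for m in months]
    for prev, cur in zip(periods, periods[1:]):
        if cur != prev + 1:
            raise ValueError("common month range is not contiguous")
    return months


def monthly_cluster_series(
    records: pd.DataFrame,
    sizes: pd.DataFrame,
    assignments: Mapping[str, str] | pd.Series,
    chapter: int | None = None,
    section: int | None = None,
) -> dict[str, MonthlySeries]:
    """Per-cluster monthly items-per-patient series at the requested level.

    The numerator pools items over the cluster's practices at the level
    (all chapters, one chapter, or one chapter+section); the denominator
    pools the registered patients of the same practices that month.
    """
    labels = pd.Series(dict(assignments) if not isinstance(assignments, pd.Series)
                       else assignments)
    unlabelled = sorted(set(records["practice_id"]) - set(labels.index))
    if unlabelled:
        raise KeyError(f"practices without a cluster label: {unlabelled}")
    months = _common_months(records, sizes)

    sel = records[records["year_month"].isin(months)]
    if chapter is not None:
        sel = sel[sel["bnf_chapter"] == chapter]
        if section is not None:
            sel = sel[sel["bnf_section"] == section]
    elif section is not None:
        raise ValueError("section filter requires a chapter")

    sizes_in = sizes[sizes["year_month"].isin(months)
                     & sizes["practice_id"].isin(labels.index)].copy()
    sizes_in["label"] = sizes_in["practice_id"].map(labels)
    patients = sizes_in.groupby(["label", "year_month"])["registered_patients"].sum()

    sel = sel.copy()
    sel["label"] = sel["practice_id"].map(labels)
    items = sel.groupby(["label", "year_month"])["items"].sum()

    level = None if chapter is None else ((chapter,) if section is None else (chapter, section))
    out: dict[str, MonthlySeries] = {}
    for label in sorted(labels.unique()):
        denom = patients.get(label)
        if denom is None:
            raise ValueError(f"cluster {label!r} has no size data")
        denom = denom.reindex(months)
        if denom.isna().any() or (denom <= 0).any():
            missing = denom[denom.isna() | (denom <= 0)].index.tolist()
            raise ValueError(f"cluster {label!r} has zero/missing patients in {missing}")
        numer = items.get(label)
        numer = (numer.reindex(months).fillna(0.0) if numer is not None
                 else pd.Series(0.0, index=months))
        out[label] = MonthlySeries(label=label, level=level, months=months,
                                   values=(numer / denom).to_numpy())
    return out


def rmse(a: MonthlySeries, b: MonthlySeries) -> float:
    """Root-mean-square difference between two aligned monthly series."""
    if a.months != b.months:
        raise ValueError("series months are not aligned")
    return float(np.sqrt(np.mean((a.values - b.values) ** 2)))


def chapter_rmse_ranking(
    records: pd.DataFrame,
    sizes: pd.DataFrame,
    assignments: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Between-cluster RMSE per BNF chapter, sorted descending (ties by chapter)."""
    labels = pd.Series(dict(assignments) if not isinstance(assignments, pd.Series)
                       else assignments)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"chapter ranking needs exactly two clusters, got {uniq}")
    rows = []
    for chapter in sorted(records["bnf_chapter"].unique()):
        series = monthly_cluster_series(records, sizes, labels, chapter=int(chapter))
        rows.append({"bnf_chapter": int(chapter),
                     "rmse": rmse(series[uniq[0]], series[uniq[1]])})
    frame = pd.DataFrame(rows)
    return (frame.sort_values(["rmse", "bnf_chapter"], ascending=[False, True])
                 .reset_index(drop=True))


def section_rmse_ranking(
    records: pd.DataFrame,
    sizes: pd.DataFrame,
    assignments: Mapping[str, str] | pd.Series,
    chapter: int,
) -> pd.DataFrame:
    """Between-cluster RMSE per section within one chapter, sorted descending."""
    labels = pd.Series(dict(assignments) if not isinstance(assignments, pd.Series)
                       else assignments)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"section ranking needs exactly two clusters, got {uniq}")
    in_chapter = records[records["bnf_chapter"] == chapter]
    rows = []
    for section in sorted(in_chapter["bnf_section"].unique()):
        series = monthly_cluster_series(records, sizes, labels,
                                        chapter=chapter, section=int(section))
        rows.append({"bnf_section": int(section),
                     "rmse": rmse(series[uniq[0]], series[uniq[1]])})
    frame = pd.DataFrame(rows)
    return (frame.sort_values(["rmse", "bnf_section"], ascending=[False, True])
                 .reset_index(drop=True))


def _practice_annual_rate(records: pd.DataFrame, sizes: pd.DataFrame,
                          months: list[str]) -> pd.Series:
    """Per-practice annualised items-per-patient over the common months."""
    n_months = len(months)
    items = (records[records["year_month"].isin(months)]
             .groupby("practice_id")["items"].sum())
    patients = (sizes[sizes["year_month"].isin(months)]
                .groupby("practice_id")["registered_patients"].mean())
    items = items.reindex(patients.index).fillna(0.0)
    return (items / patients) * (12.0 / n_months)


def section_ttests(
    records: pd.DataFrame,
    sizes: pd.DataFrame,
    assignments: Mapping[str, str] | pd.Series,
    chapter: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t-tests on per-practice annual items-per-patient, per section.

    Observations are one per practice (annualised section rate) to avoid
    pseudo-replication across months.  Raw p values are reported with
    Benjamini-Hochberg adjusted values alongside; sections with fewer than
    two practices per cluster are skipped with a warning.
    """
    labels = pd.Series(dict(assignments) if not isinstance(assignments, pd.Series)
                       else assignments)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"t-tests need exactly two clusters, got {uniq}")
    months = _common_months(records, sizes)
    in_chapter = records[records["bnf_chapter"] == chapter]

    rows = []
    for section in sorted(in_chapter["bnf_section"].unique()):
        sec = in_chapter[in_chapter["bnf_section"] == section]
        rates = _practice_annual_rate(sec, sizes[sizes["practice_id"].isin(labels.index)],
                                      months)
        has_data = set(sec["practice_id"])
        groups = []
        for label in uniq:
            ids = [p for p in labels.index[labels == label] if p in has_data]
            groups.append(rates.reindex(ids).dropna().to_numpy())
        if any(len(g) < 2 for g in groups):
            logger.warning("section %s skipped: fewer than 2 practices per cluster", section)
            continue
        t_stat, p_value = stats.ttest_ind(groups[0], groups[1], equal_var=False)
        rows.append({
            "bnf_section": int(section),
            "n_" + uniq[0]: len(groups[0]),
            "n_" + uniq[1]: len(groups[1]),
            "mean_" + uniq[0]: float(np.mean(groups[0])),
            "mean_" + uniq[1]: float(np.mean(groups[1])),
            "t_statistic": float(t_stat),
            "p_value": float(p_value),
        })
    frame = pd.DataFrame(rows)
    if not frame.empty:
        _, adjusted, _, _ = multipletests(frame["p_value"], method="fdr_bh")
        frame["p_adjusted"] = adjusted
        frame["significant"] = frame["p_value"] < alpha
    return frame
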