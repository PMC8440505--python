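"""Deprivation quartile assignment and cluster cross-tabulation.

Wards are split into quartiles Q1 (least deprived) to Q4 (most deprived)
from their deprivation ranks; clusters are cross-tabulated as percentage
rows over Q1-Q4, with a size-weighted all-practices row.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

QUARTILES = ["Q1", "Q2", "Q3", "Q4"]

#: rank 1 is the most deprived ward (NI Multiple Deprivation Measure convention)
RANK1_MOST_DEPRIVED = "rank1_most_deprived"
RANK1_LEAST_DEPRIVED = "rank1_least_deprived"


def assign_quartiles(
    ward_ranks: Mapping[str, int],
    rank_direction: str = RANK1_MOST_DEPRIVED,
) -> dict[str, str]:
    """Quartile per ward from deprivation ranks (a permutation of 1..W).

    Wards are ordered from least to most deprived and split into four
    near-equal groups (sizes differ by at most one, remainder allocated to
    the lower quartile numbers): first group Q1 (least deprived), last Q4
    (most deprived).
    """
    if rank_direction not in (RANK1_MOST_DEPRIVED, RANK1_LEAST_DEPRIVED):
        raise ValueError(f"unknown rank_direction {rank_direction!r}")
    wards = list(ward_ranks)
    ranks = [ward_ranks[w] for w in wards]
    w = len(wards)
    if sorted(ranks) != list(range(1, w + 1)):
        raise ValueError("deprivation ranks must be a permutation of 1..W with no duplicates")
    # least deprived first
    reverse = rank_direction == RANK1_MOST_DEPRIVED
    ordered = sorted(wards, key=ward_ranks.__getitem__, reverse=reverse)
    out: dict[str, str] = {}
    for q, chunk in zip(QUARTILES, np.array_split(np.array(ordered, dtype=object), 4)):
        for ward in chunk:
            out[ward] = q
    return out


def deprivation_crosstab(
    assignments: Mapping[str, str] | pd.Series,
    practice_wards: Mapping[str, str] | pd.Series,
    quartiles: Mapping[str, str],
) -> pd.DataFrame:
    """Percentage of each cluster's practices in quartiles Q1-Q4.

    Rows are cluster labels, columns Q1-Q4; each row sums to 100.
    """
    labels = pd.Series(dict(assignments) if not isinstance(assignments, pd.Series)
                       else assignments)
    wards = pd.Series(dict(practice_wards) if not isinstance(practice_wards, pd.Series)
                      else practice_wards)
    unmapped = sorted(set(labels.index) - set(wards.index))
    if unmapped:
        raise KeyError(f"practices without a ward: {unmapped}")
    practice_q = wards.reindex(labels.index).map(quartiles)
    if practice_q.isna().any():
        bad = sorted(wards.reindex(labels.index)[practice_q.isna()].unique())
        raise KeyError(f"wards without a quartile: {bad}")
    counts = (pd.crosstab(labels, practice_q)
              .reindex(columns=QUARTILES, fill_value=0))
    counts.index.name = "label"
    counts.columns.name = None
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return pct


def overall_row(cluster_rows: pd.DataFrame, cluster_sizes: Mapping[str, int]) -> pd.Series:
    """Size-weighted average of per-cluster quartile percentage rows."""
    missing = sorted(set(cluster_rows.index) - set(cluster_sizes))
    extra = sorted(set(cluster_sizes) - set(cluster_rows.index))
    if missing or extra:
        raise ValueError(f"cluster size mismatch: missing={missing} extra={extra}")
    sizes = pd.Series(cluster_sizes).reindex(cluster_rows.index).astype(float)
    weighted = cluster_rows.mul(sizes, axis=0).sum(axis=0) / sizes.sum()
    weighted.name = "All practices"
    return weighted[QUARTILES]


def top_two_quartile_share(cluster_row: Mapping[str, float] | pd.Series) -> float:
    """Share of a cluster's practices in the two most-deprived quartiles (Q3+Q4)."""
    row = pd.Series(dict(cluster_row) if not isinstance(cluster_row, pd.Series)
                    else cluster_row)
    missing = [q for q in QUARTILES if q not in row.index]
    if missing:
        raise ValueError(f"row missing quartiles: {missing}")
    return float(row["Q3"] + row["Q4"])


def deprivation_table(
    assignments: Mapping[str, str] | pd.Series,
    practice_wards: Mapping[str, str] | pd.Series,
    quartiles: Mapping[str, str],
) -> pd.DataFrame:
    """Cross-tab with the all-practices row appended (Table-style report)."""
    labels = pd.Series(dict(assignments) if not isinstance(assignments, pd.Series)
                       else assignments)
    rows = deprivation_crosstab(labels, practice_wards, quartiles)
    sizes = labels.value_counts().to_dict()
    overall = overall_row(rows, sizes)
    return pd.concat([rows, overall.to_frame().T])
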