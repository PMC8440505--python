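"""Per-practice feature derivation over a 12-month window.

Produces the six clustering features for each practice: unique pharmacy
count, annual items per registered patient, item-weighted median and
item-weighted population SD of the practice-to-pharmacy distance,
population density of the practice's area, and mean registered patients.
Also computes the pharmacy dispersion statistic (mean pairwise distance
between a practice's pharmacies).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .geospatial import GridPoint, attach_area_attributes, distance_km_arrays

logger = logging.getLogger(__name__)

#: Canonical feature order used throughout clustering and reporting.
FEATURE_ORDER = [
    "n_pharmacies",
    "items_per_patient",
    "median_distance_km",
    "sd_distance_km",
    "population_density",
    "registered_patients",
]


def month_window(start: str, n_months: int = 12) -> list[str]:
    """``n_months`` consecutive calendar months starting at ``start`` (YYYY-MM)."""
    start_period = pd.Period(start, freq="M")
    return [str(start_period + i) for i in range(n_months)]


def _check_consecutive(window: Sequence[str]) -> list[pd.Period]:
    periods = [pd.Period(m, freq="M") for m in window]
    for prev, cur in zip(periods, periods[1:]):
        if cur != prev + 1:
            raise ValueError(f"window months not consecutive at {prev}->{cur}")
    return periods


def unique_pharmacy_count(records: pd.DataFrame) -> int:
    """Number of distinct pharmacies dispensing for one practice.

    Duplicated practice-pharmacy rows across months count once.  An empty
    record set yields 0 with a warning (such practices are excluded
    downstream).
    """
    if records.empty:
        logger.warning("unique_pharmacy_count: empty record set")
        return 0
    return int(records["pharmacy_id"].nunique())


def annual_items_per_patient(records: pd.DataFrame, sizes: pd.DataFrame) -> float:
    """Items dispensed per registered patient over a 12-month window.

    ``(sum of items) / (mean monthly registered patients)`` for a single
    practice; both tables must already be restricted to the window.
    """
    if sizes.empty:
        raise ValueError("no registered-patient data overlapping the window")
    if (sizes["registered_patients"] <= 0).any():
        raise ValueError("registered_patients must be positive")
    total_items = float(records["items"].sum()) if not records.empty else 0.0
    mean_patients = float(sizes["registered_patients"].mean())
    return total_items / mean_patients


def _validate_weights(values, weights) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights)
    if v.size == 0:
        raise ValueError("empty input")
    if v.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if not np.issubdtype(w.dtype, np.integer):
        if not np.all(w == np.floor(w)):
            raise ValueError("weights must be integers")
        w = w.astype(np.int64)
    if (w < 1).any():
        raise ValueError("weights must be >= 1")
    return v, w.astype(np.int64)


def weighted_median(values, weights) -> float:
    """Median of the multiset formed by repeating each value by its weight.

    For an even total weight, the mean of the two central values of the
    expanded multiset.
    """
    v, w = _validate_weights(values, weights)
    order = np.argsort(v, kind="mergesort")
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    total = int(cum[-1])
    if total % 2 == 1:
        return float(v[np.searchsorted(cum, (total + 1) // 2)])
    lo = v[np.searchsorted(cum, total // 2)]
    hi = v[np.searchsorted(cum, total // 2 + 1)]
    return float((lo + hi) / 2.0)


def weighted_sd(values, weights) -> float:
    """Population standard deviation of the weight-expanded multiset."""
    v, w = _validate_weights(values, weights)
    total = int(w.sum())
    if total < 2:
        raise ValueError("total weight must be >= 2")
    mean = float(np.average(v, weights=w))
    var = float(np.average((v - mean) ** 2, weights=w))
    return float(np.sqrt(var))


def distance_profile(
    records: pd.DataFrame,
    practice_pt: GridPoint,
    pharmacy_pts: Mapping[str, GridPoint],
) -> tuple[float, float]:
    """Item-weighted (median, population SD) of practice-to-pharmacy distance.

    Each dispensed item counts as one journey, so per-record distances are
    weighted by that record's item count.  Records with zero items carry no
    weight and are dropped.
    """
    unresolved = sorted(set(records["pharmacy_id"]) - set(pharmacy_pts))
    if unresolved:
        raise KeyError(f"pharmacies without coordinates: {unresolved}")
    weighted = records[records["items"] > 0]
    if weighted.empty:
        raise ValueError("all item counts are zero; distance profile undefined")
    pts = [pharmacy_pts[p] for p in weighted["pharmacy_id"]]
    dists = distance_km_arrays(
        [p.easting for p in pts], [p.northing for p in pts],
        practice_pt.easting, practice_pt.northing,
    )
    w = weighted["items"].to_numpy()
    if int(w.sum()) < 2:
        return float(dists[0]), 0.0
    return weighted_median(dists, w), weighted_sd(dists, w)


def pharmacy_dispersion(points: Iterable[GridPoint]) -> float:
    """Mean distance over all unordered pairs of distinct pharmacies (km).

    Undefined (NaN) for fewer than two pharmacies.
    """
    pts = list(points)
    if len(pts) < 2:
        return float("nan")
    xy = np.array([[p.easting, p.northing] for p in pts], dtype=float)
    return float(pdist(xy).mean() / 1000.0)


def cluster_dispersion_summary(
    labels: Mapping[str, str] | pd.Series,
    dispersions: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """Per-cluster mean and sample SD of per-practice pharmacy dispersion.

    Missing (NaN) dispersion values are excluded and counted.  A cluster
    with no valid value at all is an error; a single-practice cluster
    reports its value as the mean with SD missing.
    """
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    disp = pd.Series(dict(dispersions) if not isinstance(dispersions, pd.Series) else dispersions)
    unlabelled = disp.index.difference(labels.index)
    if len(unlabelled):
        raise KeyError(f"practices without a cluster label: {sorted(unlabelled)}")
    rows = []
    for label, members in disp.groupby(labels.reindex(disp.index)):
        valid = members.dropna()
        if valid.empty:
            raise ValueError(f"cluster {label!r} has no valid dispersion values")
        rows.append({
            "label": label,
            "n_practices": int(len(members)),
            "n_missing": int(members.isna().sum()),
            "mean_dispersion_km": float(valid.mean()),
            "sd_dispersion_km": float(valid.std(ddof=1)) if len(valid) > 1 else float("nan"),
        })
    return pd.DataFrame(rows).sort_values("label").reset_index(drop=True)


def practice_dispersions(
    dispensing: pd.DataFrame,
    pharmacy_pts: Mapping[str, GridPoint],
) -> pd.Series:
    """Pharmacy dispersion for every practice in a dispensing table."""
    out = {}
    for practice, group in dispensing.groupby("practice_id"):
        ids = group["pharmacy_id"].unique()
        out[practice] = pharmacy_dispersion(pharmacy_pts[p] for p in ids)
    return pd.Series(out, name="dispersion_km")


def build_practice_profiles(
    dispensing: pd.DataFrame,
    sizes: pd.DataFrame,
    coords: Mapping[str, GridPoint],
    areas: pd.DataFrame,
    window: Sequence[str],
    *,
    practice_locations: Mapping[str, str] | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Collate the six clustering features for every retained practice.

    Only practices with dispensing activity in all 12 window months are
    retained.  ``practice_locations`` maps practice IDs to the location
    codes used in ``areas``; by default the practice ID is its own
    location code.
    """
    periods = _check_consecutive(window)
    if len(periods) != 12:
        raise ValueError(f"window must span exactly 12 months, got {len(periods)}")
    window_set = set(window)

    d = dispensing[dispensing["year_month"].isin(window_set)]
    months_present = d.groupby("practice_id")["year_month"].nunique()
    retained = sorted(months_present[months_present == 12].index)
    logger.info("retained %d of %d practices present in all 12 window months",
                len(retained), months_present.size)
    if not retained:
        raise ValueError("no practice present in all 12 window months")
    d = d[d["practice_id"].isin(retained)]
    s = sizes[sizes["year_month"].isin(window_set) & sizes["practice_id"].isin(retained)]

    missing_coords = sorted({p for p in retained if p not in coords})
    if missing_coords:
        raise KeyError(f"practices without coordinates: {missing_coords}")

    # vectorised per-record distances
    d = d.copy()
    pe = np.array([coords[p].easting for p in d["practice_id"]])
    pn = np.array([coords[p].northing for p in d["practice_id"]])
    unresolved = sorted(set(d["pharmacy_id"]) - set(coords))
    if unresolved:
        raise KeyError(f"pharmacies without coordinates: {unresolved}")
    he = np.array([coords[p].easting for p in d["pharmacy_id"]])
    hn = np.array([coords[p].northing for p in d["pharmacy_id"]])
    d["distance_km"] = distance_km_arrays(pe, pn, he, hn)

    rows = []
    size_groups = dict(tuple(s.groupby("practice_id")))
    for practice, group in d.groupby("practice_id"):
        psizes = size_groups.get(practice)
        if psizes is None or psizes.empty:
            raise ValueError(f"practice {practice!r} has no size data in window")
        active = group[group["items"] > 0]
        if active.empty:
            raise ValueError(f"practice {practice!r} has zero items across the window")
        w = active["items"].to_numpy()
        dist = active["distance_km"].to_numpy()
        rows.append({
            "practice_id": practice,
            "n_pharmacies": unique_pharmacy_count(group),
            "items_per_patient": annual_items_per_patient(group, psizes),
            "median_distance_km": weighted_median(dist, w),
            "sd_distance_km": weighted_sd(dist, w) if w.sum() >= 2 else 0.0,
            "registered_patients": float(psizes["registered_patients"].mean()),
        })
    profiles = pd.DataFrame(rows)

    if practice_locations is None:
        profiles["location_code"] = profiles["practice_id"]
    else:
        profiles["location_code"] = profiles["practice_id"].map(practice_locations)
    enriched = attach_area_attributes(profiles, areas, strict=strict)
    enriched = enriched.rename(columns={"population_density_km2": "population_density"})
    cols = ["practice_id"] + FEATURE_ORDER
    return enriched[cols].sort_values("practice_id").reset_index(drop=True)
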