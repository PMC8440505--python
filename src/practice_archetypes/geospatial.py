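"""Planar coordinate handling and area-attribute linkage.

Coordinates are eastings/northings in metres on a planar national grid
(OSGB-style).  All distances are Euclidean on that plane, reported in
kilometres.  No reprojection or spherical geometry is attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COORDINATE_COLUMNS = ["location_code", "easting_m", "northing_m"]
AREA_COLUMNS = ["location_code", "population_density_km2", "deprivation_rank"]


@dataclass(frozen=True)
class GridPoint:
    """A point on the planar national grid, in metres."""

    easting: float
    northing: float

    def __post_init__(self) -> None:
        for name, value in (("easting", self.easting), ("northing", self.northing)):
            if not math.isfinite(value):
                raise ValueError(f"GridPoint {name} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"GridPoint {name} must be >= 0, got {value!r}")


def distance_km(a: GridPoint, b: GridPoint) -> float:
    """Euclidean distance between two grid points, in kilometres.

    sqrt((delta northing)^2 + (delta easting)^2) / 1000, with coordinates
    in metres.  Symmetric and non-negative by construction.
    """
    return math.hypot(a.easting - b.easting, a.northing - b.northing) / 1000.0


def distance_km_arrays(e1, n1, e2, n2) -> np.ndarray:
    """Vectorised :func:`distance_km` on coordinate arrays (metres in, km out)."""
    e1 = np.asarray(e1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if not (np.isfinite(e1).all() and np.isfinite(n1).all()
            and np.isfinite(e2).all() and np.isfinite(n2).all()):
        raise ValueError("non-finite coordinate in distance computation")
    return np.hypot(e1 - e2, n1 - n2) / 1000.0


def load_coordinate_lookup(source) -> dict[str, GridPoint]:
    """Read a ``location_code,easting_m,northing_m`` table into a mapping.

    ``source`` may be a path to a CSV file or an already-parsed DataFrame.
    Duplicate codes and unparseable coordinates are rejected.
    """
    if isinstance(source, pd.DataFrame):
        table = source.copy()
    else:
        table = pd.read_csv(source, dtype={"location_code": str})
    missing = [c for c in COORDINATE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"coordinate lookup missing columns: {missing}")

    dupes = table["location_code"][table["location_code"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"duplicate location codes in coordinate lookup: {sorted(dupes)}")

    mapping: dict[str, GridPoint] = {}
    for row_number, row in enumerate(table.itertuples(index=False), start=1):
        try:
            easting = float(row.easting_m)
            northing = float(row.northing_m)
            if not (math.isfinite(easting) and math.isfinite(northing)):
                raise ValueError("non-finite")
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"unparseable coordinate at row {row_number} "
                f"(location_code={row.location_code!r})"
            ) from exc
        mapping[str(row.location_code)] = GridPoint(easting, northing)
    return mapping


def load_area_attributes(source) -> pd.DataFrame:
    """Read a ``location_code,population_density_km2,deprivation_rank`` table.

    Validates density non-negativity and that deprivation ranks form a
    permutation of 1..W.
    """
    if isinstance(source, pd.DataFrame):
        table = source.copy()
    else:
        table = pd.read_csv(source, dtype={"location_code": str})
    missing = [c for c in AREA_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"area attribute table missing columns: {missing}")
    table["location_code"] = table["location_code"].astype(str)
    if (table["population_density_km2"] < 0).any():
        raise ValueError("population density must be >= 0")
    ranks = table["deprivation_rank"].to_numpy()
    w = len(ranks)
    if w and sorted(ranks.tolist()) != list(range(1, w + 1)):
        raise ValueError("deprivation ranks must be a permutation of 1..W")
    return table


def attach_area_attributes(
    practices: pd.DataFrame,
    attrs: pd.DataFrame,
    *,
    on: str = "location_code",
    strict: bool = True,
) -> pd.DataFrame:
    """Left-join area attributes onto a practice table by location code.

    Strict mode (default) raises if any practice code is absent from
    ``attrs``; permissive mode drops and logs unmatched rows.  Never
    duplicates practice rows.
    """
    if on not in practices.columns:
        raise ValueError(f"practice table has no {on!r} column")
    if attrs[on].duplicated().any():
        raise ValueError("area attribute table has duplicate location codes")

    known = set(attrs[on])
    unmatched = sorted(set(practices[on]) - known)
    if unmatched:
        if strict:
            raise KeyError(f"practices with unmatched location codes: {unmatched}")
        logger.warning("dropping %d practices with unmatched location codes: %s",
                       len(unmatched), unmatched)
        practices = practices[practices[on].isin(known)]

    merged = practices.merge(attrs, on=on, how="left", validate="many_to_one")
    assert len(merged) == len(practices)
    return merged
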