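"""Synthetic cohort generation with known ground truth.

Two practice archetypes ("Metropolitan" / "Non-Metropolitan") are
parameterised by per-feature means/SDs, a deprivation quartile mix, a BNF
chapter/section item mix, a pharmacy dispersion target and a missing-BNF
rate.  The generator works at two levels:

* feature level — draw the six clustering features directly from
  truncated per-archetype Gaussians (fast clustering tests);
* record level — realise full monthly dispensing, prescribing, practice
  size, coordinate and area-attribute tables whose extracted features
  recover the sampled per-practice targets.

Pharmacies are placed around each practice at uniform angles with
log-normal radii whose median equals the practice's sampled
median-distance target; the log-scale is calibrated by Monte Carlo so the
mean pairwise pharmacy distance matches the archetype's dispersion
target.  All randomness flows from one seed through spawned substreams,
so tables can be regenerated independently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import pdist
from scipy.stats import norm

from .features import FEATURE_ORDER, month_window

logger = logging.getLogger(__name__)

BNF_CHAPTERS = list(range(1, 15))
CHAPTER4_SECTIONS = list(range(1, 12))
QUARTILE_NAMES = ["Q1", "Q2", "Q3", "Q4"]

_DEFAULT_JITTER_SEED = 20210914  # fixed: default chapter mixes are constants


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ArchetypeSpec:
    """Generative parameters for one practice archetype.

    ``feature_means``/``feature_sds`` follow :data:`FEATURE_ORDER`:
    n_pharmacies, items_per_patient, median_distance_km, sd_distance_km,
    population_density, registered_patients.
    """

    label: str
    n_practices: int
    feature_means: tuple[float, ...]
    feature_sds: tuple[float, ...]
    deprivation_mix: tuple[float, float, float, float]
    chapter_mix: dict[int, float]
    chapter4_section_mix: dict[int, float]
    dispersion_target_km: float
    missing_bnf_rate: float = 0.0024

    def __post_init__(self) -> None:
        if self.n_practices <= 0:
            raise ValueError("n_practices must be positive")
        if len(self.feature_means) != 6 or len(self.feature_sds) != 6:
            raise ValueError("feature_means and feature_sds must have 6 entries")
        if any(sd < 0 for sd in self.feature_sds):
            raise ValueError("feature SDs must be non-negative")
        if self.dispersion_target_km <= 0:
            raise ValueError("dispersion target must be positive")
        if not 0.0 <= self.missing_bnf_rate < 1.0:
            raise ValueError("missing_bnf_rate must be in [0, 1)")
        for name, probs in (("deprivation_mix", self.deprivation_mix),
                            ("chapter_mix", tuple(self.chapter_mix.values())),
                            ("chapter4_section_mix",
                             tuple(self.chapter4_section_mix.values()))):
            if any(p < 0 for p in probs):
                raise ValueError(f"{name} has negative entries")
            if not math.isclose(sum(probs), 1.0, abs_tol=0.01):
                raise ValueError(f"{name} must sum to 1, got {sum(probs)}")

    def normalised(self) -> "ArchetypeSpec":
        """Copy with probability vectors renormalised to sum exactly to 1."""
        dep = np.array(self.deprivation_mix, dtype=float)
        ch = dict(self.chapter_mix)
        sec = dict(self.chapter4_section_mix)
        ch_total = sum(ch.values())
        sec_total = sum(sec.values())
        return replace(
            self,
            deprivation_mix=tuple(dep / dep.sum()),
            chapter_mix={k: v / ch_total for k, v in ch.items()},
            chapter4_section_mix={k: v / sec_total for k, v in sec.items()},
        )


def _chapter_mix(chapter4_share: float, jitter_rng: np.random.Generator) -> dict[int, float]:
    """Chapter 4 gets a fixed share; others split the remainder with +/-10% jitter."""
    others = [c for c in BNF_CHAPTERS if c != 4]
    weights = (1.0 + jitter_rng.uniform(-0.10, 0.10, len(others)))
    weights *= (1.0 - chapter4_share) / weights.sum()
    mix = {4: chapter4_share}
    mix.update({c: float(w) for c, w in zip(others, weights)})
    return mix


def _section_mixes(met_ch4: float, nonmet_ch4: float) -> tuple[dict[int, float], dict[int, float]]:
    """Within-chapter-4 section shares.

    Non-Metropolitan sections are uniform; the Metropolitan excess chapter
    share is carried by section 7 (60%) and section 3 (40%), so those two
    sections dominate the between-cluster section differences.
    """
    n = len(CHAPTER4_SECTIONS)
    base_abs = nonmet_ch4 / n
    excess = met_ch4 - nonmet_ch4
    met_abs = {s: base_abs for s in CHAPTER4_SECTIONS}
    met_abs[7] += 0.6 * excess
    met_abs[3] += 0.4 * excess
    met_mix = {s: v / met_ch4 for s, v in met_abs.items()}
    nonmet_mix = {s: 1.0 / n for s in CHAPTER4_SECTIONS}
    return met_mix, nonmet_mix


def default_archetypes() -> tuple[ArchetypeSpec, ArchetypeSpec]:
    """The two built-in archetypes (90 Metropolitan + 243 Non-Metropolitan)."""
    jitter = np.random.default_rng(_DEFAULT_JITTER_SEED)
    met_section_mix, nonmet_section_mix = _section_mixes(0.20, 0.16)
    metropolitan = ArchetypeSpec(
        label="Metropolitan",
        n_practices=90,
        feature_means=(212.0, 268.8, 4.6, 13.1, 5180.0, 5645.0),
        feature_sds=(46.8, 5.8, 1.5, 3.4, 2578.0, 2724.0),
        deprivation_mix=(0.233, 0.044, 0.200, 0.522),
        chapter_mix=_chapter_mix(0.20, jitter),
        chapter4_section_mix=met_section_mix,
        dispersion_target_km=26.2,
    ).normalised()
    non_metropolitan = ArchetypeSpec(
        label="Non-Metropolitan",
        n_practices=243,
        feature_means=(98.0, 246.0, 14.8, 19.8, 1272.0, 6030.0),
        feature_sds=(38.4, 3.4, 5.9, 5.9, 1230.0, 2859.0),
        deprivation_mix=(0.259, 0.325, 0.278, 0.139),
        chapter_mix=_chapter_mix(0.16, jitter),
        chapter4_section_mix=nonmet_section_mix,
        dispersion_target_km=40.4,
    ).normalised()
    return metropolitan, non_metropolitan


# ---------------------------------------------------------------------------
# feature-level sampling


def _truncate_features(draws: np.ndarray) -> np.ndarray:
    """Clip sampled features to physically meaningful bounds, in place."""
    out = draws.copy()
    out[:, 0] = np.maximum(1, np.rint(out[:, 0]))        # n_pharmacies
    out[:, 1] = np.maximum(1.0, out[:, 1])               # items_per_patient
    out[:, 2] = np.maximum(0.1, out[:, 2])               # median distance
    out[:, 3] = np.maximum(out[:, 3], 0.05 * out[:, 2])  # sd >= 5% of median
    out[:, 3] = np.maximum(0.0, out[:, 3])
    out[:, 4] = np.maximum(1.0, out[:, 4])               # density
    out[:, 5] = np.maximum(100.0, np.rint(out[:, 5]))    # registered patients
    return out


def _mixture_standardisation(archetypes: Sequence[ArchetypeSpec]):
    """Theoretical mean/SD of the archetype mixture, and archetype centres."""
    mus = np.array([a.feature_means for a in archetypes])
    sds = np.array([a.feature_sds for a in archetypes])
    w = np.array([a.n_practices for a in archetypes], dtype=float)
    w /= w.sum()
    mix_mu = (w[:, None] * mus).sum(axis=0)
    mix_var = (w[:, None] * (sds ** 2 + mus ** 2)).sum(axis=0) - mix_mu ** 2
    mix_sd = np.sqrt(mix_var)
    centres = (mus - mix_mu) / mix_sd
    return mix_mu, mix_sd, centres


def sample_feature_level(
    archetypes: Sequence[ArchetypeSpec],
    seed,
    separation_margin: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Draw per-practice features from the archetypes' truncated Gaussians.

    With exactly two archetypes, draws landing on (or within
    ``separation_margin`` of) the wrong side of the midpoint boundary
    between the archetype centres, in mixture-standardised space, are
    redrawn.  The cluster archetypes describe the two cells of a k-means
    partition, whose members by construction lie on their own centroid's
    side of the boundary; without this constraint a few boundary crossings
    per cohort would make exact label recovery impossible.

    Returns (feature table, true labels, per-practice targets); at feature
    level the targets equal the features.
    """
    if not archetypes:
        raise ValueError("need at least one archetype")
    rng = _rng(seed)
    enforce = len(archetypes) == 2 and separation_margin is not None
    if enforce:
        mix_mu, mix_sd, centres = _mixture_standardisation(archetypes)
    frames, labels = [], []
    offset = 0
    for arch_index, arch in enumerate(archetypes):
        means = np.array(arch.feature_means)
        sds = np.array(arch.feature_sds)
        draws = rng.normal(means, sds, size=(arch.n_practices, 6))
        # winsorise at +/- 3 SD: a handful of extreme draws would otherwise
        # blur the archetype separation the downstream recovery checks assume
        draws = np.clip(draws, means - 3.0 * sds, means + 3.0 * sds)
        if enforce:
            for i in range(arch.n_practices):
                for _ in range(1000):
                    z = (draws[i] - mix_mu) / mix_sd
                    d = ((z - centres) ** 2).sum(axis=1)
                    if d[arch_index] + separation_margin <= d[1 - arch_index]:
                        break
                    redraw = rng.normal(means, sds)
                    draws[i] = np.clip(redraw, means - 3.0 * sds, means + 3.0 * sds)
                else:
                    raise RuntimeError("could not draw a separated practice; "
                                       "archetypes overlap too strongly")
        values = _truncate_features(draws)
        ids = [f"P{offset + i + 1:04d}" for i in range(arch.n_practices)]
        frame = pd.DataFrame(values, columns=FEATURE_ORDER)
        frame.insert(0, "practice_id", ids)
        frames.append(frame)
        labels.extend([arch.label] * arch.n_practices)
        offset += arch.n_practices
    features = pd.concat(frames, ignore_index=True)
    truth = pd.Series(labels, index=features["practice_id"], name="archetype")
    return features, truth, features.copy()


# ---------------------------------------------------------------------------
# pharmacy geometry and dispersion calibration


def _quantile_radii(sigma: float, n: int) -> np.ndarray:
    """Deterministic log-normal radius quantiles with median exactly 1."""
    u = (np.arange(n) + 0.5) / n
    return np.exp(sigma * norm.ppf(u))


def _mean_pairwise_unit(sigma: float, angles: np.ndarray) -> float:
    """MC mean pairwise distance for unit-median radii at the given spread.

    ``angles`` has shape (reps, n_points); fixing it across calls gives
    common random numbers, so the result is smooth and monotone in sigma.
    """
    n = angles.shape[1]
    r = _quantile_radii(sigma, n)
    total = 0.0
    for a in angles:
        pts = np.column_stack([r * np.cos(a), r * np.sin(a)])
        total += pdist(pts).mean()
    return total / len(angles)


def _dispersion_curve(sigmas: np.ndarray, n_points: int, mc_reps: int,
                      seed) -> np.ndarray:
    rng = _rng(seed)
    angles = rng.uniform(0.0, 2.0 * np.pi, size=(mc_reps, n_points))
    return np.array([_mean_pairwise_unit(s, angles) for s in sigmas])


def calibrate_radial_scale(
    dispersion_target_km: float,
    sigma: float = 0.0,
    mc_reps: int = 30,
    seed: int = 0,
    n_points: int = 256,
    tol: float = 0.02,
    bracket: tuple[float, float] = (1e-3, 1e4),
) -> float:
    """Radial scale s so that radii ``s * lognormal(sigma)`` at uniform
    angles have Monte-Carlo mean pairwise distance within ``tol`` of the
    target (bisection on s).

    With the degenerate family (sigma = 0) all radii equal s and the mean
    chord length of the circle is (4/pi) s.
    """
    if dispersion_target_km <= 0:
        raise ValueError("dispersion target must be positive")
    rng = _rng(seed)
    angles = rng.uniform(0.0, 2.0 * np.pi, size=(mc_reps, n_points))
    unit = _mean_pairwise_unit(sigma, angles)
    lo, hi = bracket
    if not (lo * unit < dispersion_target_km < hi * unit):
        raise ValueError("search interval does not bracket the target")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        value = mid * unit
        if abs(value - dispersion_target_km) <= 0.5 * tol * dispersion_target_km:
            return mid
        if value < dispersion_target_km:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_radial_sigma(
    dispersion_target_km: float,
    median_km: float,
    mc_reps: int = 30,
    seed: int = 0,
    n_points: int = 256,
    sigma_grid: np.ndarray | None = None,
) -> float:
    """Log-normal spread so radii with the given median hit the dispersion
    target (clamped to 0 when even concentric placement over-disperses)."""
    if sigma_grid is None:
        sigma_grid = np.linspace(0.0, 3.5, 36)
    curve = _dispersion_curve(sigma_grid, n_points, mc_reps, seed)
    ratio = dispersion_target_km / median_km
    if ratio <= curve[0]:
        return 0.0
    if ratio >= curve[-1]:
        raise ValueError("dispersion target unreachable within the sigma grid")
    return float(np.interp(ratio, curve, sigma_grid))


# ---------------------------------------------------------------------------
# record-level generation

#: practices are placed in this box (metres) so that even extreme pharmacy
#: radii stay on the non-negative grid
_BASE_EASTING = (1.0e6, 1.2e6)
_BASE_NORTHING = (1.0e6, 1.2e6)


@dataclass
class SyntheticCohort:
    """The five analysis input tables plus ground truth."""

    dispensing: pd.DataFrame
    prescribing: pd.DataFrame
    sizes: pd.DataFrame
    coordinates: pd.DataFrame
    areas: pd.DataFrame
    truth: pd.DataFrame
    seed: int
    months: list[str] = field(default_factory=list)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.dispensing.to_csv(out / "dispensing.csv", index=False)
        self.prescribing.to_csv(out / "prescribing.csv", index=False)
        self.sizes.to_csv(out / "sizes.csv", index=False)
        self.coordinates.to_csv(out / "coordinates.csv", index=False,
                                float_format="%.3f")
        self.areas.to_csv(out / "areas.csv", index=False, float_format="%.6g")
        self.truth.to_csv(out / "truth.csv", index=False, float_format="%.10g")


def _prescribing_cells(arch: ArchetypeSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    chapters, sections, probs = [], [], []
    for chapter, share in sorted(arch.chapter_mix.items()):
        if chapter == 4:
            for section, sec_share in sorted(arch.chapter4_section_mix.items()):
                chapters.append(4)
                sections.append(section)
                probs.append(share * sec_share)
        else:
            chapters.append(chapter)
            sections.append(1)
            probs.append(share)
    p = np.array(probs)
    return np.array(chapters), np.array(sections), p / p.sum()


def generate_records(
    archetypes: Sequence[ArchetypeSpec] | None = None,
    months: int = 12,
    seed: int = 0,
    start_month: str = "2018-04",
    include_dispensing: bool = True,
) -> SyntheticCohort:
    """Realise a full record-level cohort for the given archetypes.

    ``include_dispensing=False`` skips the dispensing/coordinate tables
    (cheap mode for prescribing-only experiments).
    """
    if months < 12:
        raise ValueError("months must be >= 12")
    if archetypes is None:
        archetypes = default_archetypes()
    ss = np.random.SeedSequence(seed)
    feat_ss, geom_ss, vol_ss, rx_ss, dep_ss, size_ss, cal_ss = ss.spawn(7)

    features, truth_labels, _ = sample_feature_level(archetypes, np.random.default_rng(feat_ss))
    month_list = month_window(start_month, months)
    practice_arch = np.repeat(np.arange(len(archetypes)),
                              [a.n_practices for a in archetypes])

    geom_rng = np.random.default_rng(geom_ss)
    vol_rng = np.random.default_rng(vol_ss)
    rx_rng = np.random.default_rng(rx_ss)
    dep_rng = np.random.default_rng(dep_ss)
    size_rng = np.random.default_rng(size_ss)

    # per-archetype radial spread: calibrated once at the archetype's mean
    # median-distance target, so per-practice dispersion scales with its
    # sampled median and the archetype-average dispersion hits the target
    sigma_grid = np.linspace(0.0, 3.5, 36)
    arch_sigmas = []
    for arch, child in zip(archetypes, cal_ss.spawn(len(archetypes))):
        n_pts = max(8, int(round(arch.feature_means[0])))
        curve = _dispersion_curve(sigma_grid, n_pts, 30, np.random.default_rng(child))
        ratio = np.clip(arch.dispersion_target_km / arch.feature_means[2],
                        curve[0], curve[-1])
        arch_sigmas.append(float(np.interp(ratio, curve, sigma_grid)))

    ids = features["practice_id"].to_numpy()
    n_pharm = features["n_pharmacies"].to_numpy().astype(int)
    ipp = features["items_per_patient"].to_numpy()
    med = features["median_distance_km"].to_numpy()
    density = features["population_density"].to_numpy()
    patients = features["registered_patients"].to_numpy().astype(int)

    # --- practice sizes: quarterly values forward-filled over months
    n_quarters = (months + 2) // 3
    size_rows = []
    monthly_patients = np.empty((len(ids), months), dtype=int)
    for i, pid in enumerate(ids):
        q_factor = 1.0 + size_rng.uniform(-0.02, 0.02, n_quarters)
        for m_idx, month in enumerate(month_list):
            value = max(100, int(round(patients[i] * q_factor[m_idx // 3])))
            monthly_patients[i, m_idx] = value
            size_rows.append((pid, month, value))
    sizes = pd.DataFrame(size_rows,
                         columns=["practice_id", "year_month", "registered_patients"])

    # --- monthly item totals (annual total fixed, +/-5% month jitter)
    annual_total = np.rint(ipp * patients * months / 12.0).astype(np.int64)
    monthly_totals = np.empty((len(ids), months), dtype=np.int64)
    for i in range(len(ids)):
        weights = 1.0 + vol_rng.uniform(-0.05, 0.05, months)
        monthly_totals[i] = vol_rng.multinomial(annual_total[i], weights / weights.sum())

    # --- geometry + dispensing
    dispensing = pd.DataFrame(columns=["practice_id", "pharmacy_id", "year_month", "items"])
    coordinates = pd.DataFrame(columns=["location_code", "easting_m", "northing_m"])
    sigmas = np.zeros(len(ids))
    if include_dispensing:
        coord_codes, coord_e, coord_n = [], [], []
        d_practice, d_pharmacy, d_month, d_items = [], [], [], []
        for i, pid in enumerate(ids):
            sigma = arch_sigmas[practice_arch[i]]
            sigmas[i] = sigma
            p_count = n_pharm[i]
            radii_km = med[i] * _quantile_radii(sigma, p_count)
            angles = geom_rng.uniform(0.0, 2.0 * np.pi, p_count)
            px = geom_rng.uniform(*_BASE_EASTING)
            py = geom_rng.uniform(*_BASE_NORTHING)
            pharm_e = px + 1000.0 * radii_km * np.cos(angles)
            pharm_n = py + 1000.0 * radii_km * np.sin(angles)
            # keep the whole constellation on the non-negative grid; a pure
            # translation, so no practice-pharmacy distance changes
            shift_e = max(0.0, -min(px, pharm_e.min()))
            shift_n = max(0.0, -min(py, pharm_n.min()))
            px, py = px + shift_e, py + shift_n
            pharm_e += shift_e
            pharm_n += shift_n
            pharm_ids = [f"{pid}-PH{j + 1:03d}" for j in range(p_count)]
            coord_codes.append(pid)
            coord_e.append(px)
            coord_n.append(py)
            coord_codes.extend(pharm_ids)
            coord_e.extend(pharm_e.tolist())
            coord_n.extend(pharm_n.tolist())
            uniform = np.full(p_count, 1.0 / p_count)
            for m_idx, month in enumerate(month_list):
                alloc = vol_rng.multinomial(monthly_totals[i, m_idx], uniform)
                nz = np.nonzero(alloc)[0]
                d_practice.extend([pid] * len(nz))
                d_pharmacy.extend(pharm_ids[j] for j in nz)
                d_month.extend([month] * len(nz))
                d_items.extend(alloc[nz].tolist())
        dispensing = pd.DataFrame({
            "practice_id": d_practice,
            "pharmacy_id": d_pharmacy,
            "year_month": d_month,
            "items": np.array(d_items, dtype=np.int64),
        })
        coordinates = pd.DataFrame({
            "location_code": coord_codes,
            "easting_m": coord_e,
            "northing_m": coord_n,
        })

    # --- prescribing records (chapter/section split of the same monthly totals)
    cells = [_prescribing_cells(a) for a in archetypes]
    r_practice, r_month, r_chapter, r_section, r_items = [], [], [], [], []
    for i, pid in enumerate(ids):
        chapters, sections, probs = cells[practice_arch[i]]
        for m_idx, month in enumerate(month_list):
            alloc = rx_rng.multinomial(monthly_totals[i, m_idx], probs)
            nz = np.nonzero(alloc)[0]
            r_practice.extend([pid] * len(nz))
            r_month.extend([month] * len(nz))
            r_chapter.extend(chapters[nz].tolist())
            r_section.extend(sections[nz].tolist())
            r_items.extend(alloc[nz].tolist())
    prescribing = pd.DataFrame({
        "practice_id": r_practice,
        "year_month": r_month,
        "bnf_chapter": pd.array(r_chapter, dtype="Int64"),
        "bnf_section": pd.array(r_section, dtype="Int64"),
        "items": np.array(r_items, dtype=np.int64),
    })
    # strip BNF info from a small fraction of rows (the chapter-99 path)
    rates = np.array([archetypes[a].missing_bnf_rate for a in practice_arch])
    rate_by_practice = pd.Series(rates, index=ids)
    row_rates = prescribing["practice_id"].map(rate_by_practice).to_numpy()
    missing_mask = rx_rng.random(len(prescribing)) < row_rates
    prescribing.loc[missing_mask, ["bnf_chapter", "bnf_section"]] = pd.NA

    # --- deprivation: one ward per practice, ranks consistent with quartiles
    quartile_idx = np.empty(len(ids), dtype=int)
    for i in range(len(ids)):
        mix = archetypes[practice_arch[i]].deprivation_mix
        quartile_idx[i] = dep_rng.choice(4, p=mix)
    # rank 1 = most deprived: Q4 wards first, uniform order within quartile
    order = np.lexsort((dep_rng.random(len(ids)), -quartile_idx))
    ranks = np.empty(len(ids), dtype=int)
    ranks[order] = np.arange(1, len(ids) + 1)
    areas = pd.DataFrame({
        "location_code": ids,
        "population_density_km2": density,
        "deprivation_rank": ranks,
    })

    truth = features.copy()
    truth["archetype"] = truth_labels.to_numpy()
    truth["deprivation_quartile"] = [QUARTILE_NAMES[q] for q in quartile_idx]
    truth["radial_sigma"] = sigmas

    logger.info("generated cohort: %d practices, %d dispensing rows, %d prescribing rows",
                len(ids), len(dispensing), len(prescribing))
    return SyntheticCohort(
        dispensing=dispensing,
        prescribing=prescribing,
        sizes=sizes,
        coordinates=coordinates,
        areas=areas,
        truth=truth,
        seed=seed,
        months=month_list,
    )


# ---------------------------------------------------------------------------
# YAML round trip for archetype specs


def archetypes_to_yaml(archetypes: Sequence[ArchetypeSpec], path) -> None:
    payload = []
    for a in archetypes:
        payload.append({
            "label": a.label,
            "n_practices": a.n_practices,
            "feature_means": [float(x) for x in a.feature_means],
            "feature_sds": [float(x) for x in a.feature_sds],
            "deprivation_mix": [float(x) for x in a.deprivation_mix],
            "chapter_mix": {int(k): float(v) for k, v in a.chapter_mix.items()},
            "chapter4_section_mix": {int(k): float(v)
                                     for k, v in a.chapter4_section_mix.items()},
            "dispersion_target_km": a.dispersion_target_km,
            "missing_bnf_rate": a.missing_bnf_rate,
        })
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def archetypes_from_yaml(path) -> list[ArchetypeSpec]:
    payload = yaml.safe_load(Path(path).read_text())
    specs = []
    for entry in payload:
        specs.append(ArchetypeSpec(
            label=entry["label"],
            n_practices=int(entry["n_practices"]),
            feature_means=tuple(float(x) for x in entry["feature_means"]),
            feature_sds=tuple(float(x) for x in entry["feature_sds"]),
            deprivation_mix=tuple(float(x) for x in entry["deprivation_mix"]),
            chapter_mix={int(k): float(v) for k, v in entry["chapter_mix"].items()},
            chapter4_section_mix={int(k): float(v)
                                  for k, v in entry["chapter4_section_mix"].items()},
            dispersion_target_km=float(entry["dispersion_target_km"]),
            missing_bnf_rate=float(entry.get("missing_bnf_rate", 0.0024)),
        ).normalised())
    return specs
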