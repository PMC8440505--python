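"""End-to-end orchestration: ingest -> features -> clustering -> prescribing -> deprivation.

A single :class:`RunConfig` drives the whole run; outputs are plain CSV
files plus a machine-readable ``summary.json``.  Identical config and
seed produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from . import clustering, deprivation, features, prescribing
from .geospatial import load_area_attributes, load_coordinate_lookup
from .synthetic_data import SyntheticCohort, default_archetypes, generate_records

logger = logging.getLogger(__name__)

_CSV_FLOAT = "%.10g"


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    out_dir: str = "outputs"
    synthetic: bool = True
    dispensing_path: str | None = None
    prescribing_path: str | None = None
    sizes_path: str | None = None
    coordinates_path: str | None = None
    areas_path: str | None = None
    clustering_window_start: str = "2018-04"
    series_window_start: str | None = None  # defaults to the clustering window
    series_months: int = 12
    k_range_max: int = 10
    seed: int = 42
    n_init: int = 50
    rank_direction: str = deprivation.RANK1_MOST_DEPRIVED
    alpha: float = 0.05
    focus_chapter: int = 4

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def _load_inputs(config: RunConfig):
    if config.synthetic:
        cohort = generate_records(default_archetypes(),
                                  months=max(12, config.series_months),
                                  seed=config.seed,
                                  start_month=config.clustering_window_start)
        coords = load_coordinate_lookup(cohort.coordinates)
        areas = load_area_attributes(cohort.areas)
        return cohort.dispensing, cohort.prescribing, cohort.sizes, coords, areas, cohort
    paths = {
        "dispensing": config.dispensing_path,
        "prescribing": config.prescribing_path,
        "sizes": config.sizes_path,
        "coordinates": config.coordinates_path,
        "areas": config.areas_path,
    }
    for name, path in paths.items():
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"missing input file for {name}: {path!r}")
    dispensing = pd.read_csv(paths["dispensing"], dtype={"practice_id": str,
                                                         "pharmacy_id": str,
                                                         "year_month": str})
    rx = pd.read_csv(paths["prescribing"], dtype={"practice_id": str, "year_month": str})
    sizes = pd.read_csv(paths["sizes"], dtype={"practice_id": str, "year_month": str})
    coords = load_coordinate_lookup(paths["coordinates"])
    areas = load_area_attributes(paths["areas"])
    return dispensing, rx, sizes, coords, areas, None


def _write(frame: pd.DataFrame, path: Path, **kwargs) -> None:
    frame.to_csv(path, index=False, float_format=_CSV_FLOAT, **kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and write all report files.

    Returns the machine-readable summary (also written as
    ``summary.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        dispensing, rx, sizes, coords, areas, cohort = _load_inputs(config)

        stage = "features"
        window = features.month_window(config.clustering_window_start, 12)
        profiles = features.build_practice_profiles(dispensing, sizes, coords,
                                                    areas, window)
        _write(profiles, out / "profiles.csv")

        stage = "clustering"
        Z, params = clustering.standardise(profiles)
        k_range = range(1, min(config.k_range_max, len(Z) - 1) + 1)
        inertias = clustering.inertia_curve(Z, k_range, config.seed, config.n_init)
        sil_range = [k for k in k_range if 2 <= k <= len(Z) - 1]
        silhouettes = clustering.silhouette_curve(Z, sil_range, config.seed,
                                                  config.n_init)
        k_elbow = clustering.select_k_elbow(inertias)
        k_sil = int(silhouettes.idxmax())
        k_chosen = k_sil if k_sil != k_elbow else k_elbow
        k_table = pd.DataFrame({"k": list(k_range),
                                "inertia": [inertias[k] for k in k_range],
                                "mean_silhouette": [silhouettes.get(k) for k in k_range]})
        _write(k_table, out / "k_selection.csv")

        model = clustering.fit_kmeans(Z, k_chosen, config.seed, config.n_init)
        if model.k == 2:
            model = clustering.label_clusters(model, params)
            labels = clustering.labelled_assignments(model)
        else:
            labels = model.assignments.map(lambda c: f"cluster_{c}").rename("label")
        assignments = pd.DataFrame({
            "practice_id": model.assignments.index,
            "cluster_index": model.assignments.to_numpy(),
            "label": labels.to_numpy(),
        })
        _write(assignments, out / "assignments.csv")

        if model.labels is not None:
            centroids = clustering.centroid_summary(model, params, profiles)
            _write(centroids, out / "centroids.csv")

        pca_scores, explained = clustering.pca_project(Z)
        pca_out = pca_scores.reset_index()
        pca_out["label"] = pca_out["practice_id"].map(labels)
        _write(pca_out, out / "pca.csv")

        stage = "dispersion"
        if not dispensing.empty:
            dispersions = features.practice_dispersions(dispensing, coords)
            summary_disp = features.cluster_dispersion_summary(labels, dispersions)
            _write(summary_disp, out / "dispersion_by_cluster.csv")

        stage = "prescribing"
        clean, excluded_fraction = prescribing.clean_bnf(rx)
        ranking = ttests = None
        if model.k == 2:
            ranking = prescribing.chapter_rmse_ranking(clean, sizes, labels)
            _write(ranking, out / "rmse_by_chapter.csv")
            series = prescribing.monthly_cluster_series(clean, sizes, labels)
            series_frame = pd.DataFrame({
                "year_month": next(iter(series.values())).months,
                **{label: s.values for label, s in series.items()},
            })
            _write(series_frame, out / "series_total.csv")
            ttests = prescribing.section_ttests(clean, sizes, labels,
                                                config.focus_chapter, config.alpha)
            _write(ttests, out / f"ttests_chapter{config.focus_chapter}.csv")

        stage = "deprivation"
        ward_ranks = dict(zip(areas["location_code"], areas["deprivation_rank"]))
        quartiles = deprivation.assign_quartiles(ward_ranks, config.rank_direction)
        practice_wards = pd.Series(assignments["practice_id"].to_numpy(),
                                   index=assignments["practice_id"]).rename("ward")
        table = deprivation.deprivation_table(labels, practice_wards, quartiles)
        table.round(1).to_csv(out / "deprivation_table.csv", index_label="label")

        stage = "summary"
        summary = {
            "version": __version__,
            "seed": config.seed,
            "n_practices": int(len(profiles)),
            "k_elbow": int(k_elbow),
            "k_silhouette": int(k_sil),
            "k_chosen": int(k_chosen),
            "inertia": float(model.inertia),
            "cluster_sizes": labels.value_counts().to_dict(),
            "excluded_bnf_fraction": float(excluded_fraction),
            "pca_explained_variance": [float(x) for x in explained],
            "top_rmse_chapter": (int(ranking.iloc[0]["bnf_chapter"])
                                 if ranking is not None and not ranking.empty else None),
            "config": asdict(config),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
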