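# practice-archetypes

Discover GP-practice archetypes from geolocational and prescribing
features, and compare the discovered clusters' prescribing behaviour by
BNF chapter/section and by area deprivation quartile.

The pipeline:

1. **Ingest** — monthly practice→pharmacy dispensing records, monthly
   BNF-coded prescribing records, monthly registered-patient counts, a
   coordinate lookup (planar easting/northing in metres) and an
   area-attribute table (population density, deprivation rank).
2. **Features** — per practice over a 12-month window: unique pharmacy
   count, annual items per registered patient, item-weighted median and
   SD of the practice-to-pharmacy distance, population density, and mean
   registered patients. Practices not present in all 12 months are
   excluded.
3. **Clustering** — z-score standardisation, k-means (k-means++, 50
   restarts), k selection by the elbow rule (maximum second-order
   difference of the inertia curve) corroborated by the mean silhouette
   coefficient, 2-D PCA for visualisation, and Metropolitan /
   Non-Metropolitan labelling by population-density centroid.
4. **Prescribing comparison** — chapter-99 cleaning of records lacking
   BNF information, per-cluster monthly items-per-patient series,
   between-cluster RMSE ranking by chapter and by section, and
   per-section Welch t-tests with Benjamini–Hochberg adjustment.
5. **Deprivation** — ward quartiles from deprivation ranks, per-cluster
   Q1–Q4 percentage rows and the size-weighted all-practices row.

A synthetic cohort generator (`practice_archetypes.synthetic_data`)
emulates all five input tables from two configurable practice
archetypes, with ground-truth labels, so every stage runs and is
testable without any external data. Pharmacy geometry is calibrated by
Monte Carlo so that each archetype's mean pairwise pharmacy distance
matches its dispersion target while the item-weighted median distance
matches each practice's sampled target.

## CLI

Generate a synthetic cohort (five input CSVs plus `truth.csv`):

```sh
archetypes generate --seed 42 --months 12 --out cohort/
```

Run the full pipeline on synthetic data (or on real files via a YAML
config mirroring `RunConfig`):

```sh
archetypes run --synthetic --seed 42 --out outputs/
archetypes run --config config.yaml
```

Outputs: `profiles.csv`, `assignments.csv`, `centroids.csv`,
`k_selection.csv`, `pca.csv`, `dispersion_by_cluster.csv`,
`rmse_by_chapter.csv`, `series_total.csv`, `ttests_chapter4.csv`,
`deprivation_table.csv` and a machine-readable `summary.json`.
Identical config and seed give byte-identical CSVs.

## Input file formats

All CSV, UTF-8, header required:

| table | columns |
| --- | --- |
| dispensing | `practice_id,pharmacy_id,year_month,items` |
| prescribing | `practice_id,year_month,bnf_chapter,bnf_section,items` (blank chapter/section allowed) |
| sizes | `practice_id,year_month,registered_patients` |
| coordinates | `location_code,easting_m,northing_m` |
| areas | `location_code,population_density_km2,deprivation_rank` |

`year_month` is ISO `YYYY-MM`; coordinates are planar metres.
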