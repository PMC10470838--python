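# phenosalt

Non-destructive salt-tolerance evaluation of plant canopies from
hyperspectral images and LiDAR point clouds.

The package extracts **computing phenotypic traits** — 16 narrow-band
vegetation indices from a calibrated reflectance cube (400–1000 nm) and
three structural traits (grid-averaged plant height, occupied-cell canopy
leaf area, convex-hull volume) from a canopy point cloud — and grades each
sample with an **entropy-weighted fuzzy comprehensive evaluation**: traits
are min-max standardized to [0, 1] (negative indicators flipped), weighted
by information-entropy divergence, mapped through trapezoidal membership
functions into four tolerance grades (scored 100/75/50/25), composed with
the weighted-average operator and rated by maximum membership. A PCA
first-component composite score, a per-trait statistics table
(CV / entropy divergence / variance contribution rate) and a
rating-consistency rate are provided for comparison.

## Layout

| module | purpose |
| --- | --- |
| `phenosalt.spectral` | ENVI/GeoTIFF cube IO, TVI-threshold vegetation segmentation (default threshold 10.6), the 16 built-in index definitions, masked-mean trait extraction |
| `phenosalt.structural` | PLY/XYZ/LAS cloud IO, statistical outlier removal, sub-canopy voxel filtering, moving-least-squares smoothing, height / leaf-area / hull-volume extractors (0.5 cm grid) |
| `phenosalt.fce` | standardization, entropy weights, trapezoidal memberships (breakpoints 0.2, 0.3, 0.45, 0.55, 0.7, 0.8), fuzzy composition and grading |
| `phenosalt.suite` | trait statistics table, PCA composite baseline, consistency rate, rank agreement |
| `phenosalt.fixtures` | seeded synthetic scenes, canopies and trait cohorts with analytic ground truth |
| `phenosalt.pipeline` / `phenosalt.cli` | run configuration, trait-table IO, end-to-end pipeline, command line |

## Command line

One entry point with subcommands:

```sh
# synthetic fixtures (scene = ENVI cube, canopy = PLY cloud, cohort = CSV)
phenosalt simulate cohort --out fixtures/

# per-sample trait extraction into a shared CSV table
phenosalt traits-hsi   --cube scene.img  --sample-id s1 --threshold 10.6 --out traits.csv
phenosalt traits-lidar --points canopy.ply --sample-id s1 --cell 0.5 --out traits.csv

# grading, statistics, PCA baseline, rating comparison
phenosalt evaluate --traits traits.csv --polarity polarity.csv --out ratings.csv --weights-out weights.json
phenosalt stats    --traits traits.csv --out stats.csv
phenosalt pca      --traits traits.csv --reference NDVI --out pca.csv
phenosalt compare  --a ratings_a.csv --b ratings_b.csv

# everything at once from a manifest (YAML: samples with cube/points paths)
phenosalt run --config config.yaml --manifest manifest.yaml --out report/
```

Trait tables are CSV with a `sample_id` column; the polarity file lists
`trait_name,positive|negative` per line (by default every trait is a
positive indicator except the Carter stress ratio CTR). `config.yaml` may
override any pipeline constant (TVI threshold, grid cell, filter
parameters, membership breakpoints, grade scores…); unknown keys are
rejected.

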