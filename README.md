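# dfcmeta

Dynamic functional-connectivity analysis of two-cohort region×time signals
through instantaneous phase-locking, with a coupled-oscillator simulator for
fully synthetic end-to-end runs.

The pipeline:

1. **signal_prep** — parcellation averaging, brick-wall FFT band-pass
   (default 0.01–0.08 Hz), Hilbert analytic phase, and a Carson-style
   narrowband (Bedrosian) validity report.
2. **leida** — timepoint-wise phase-locking matrices
   `cos(θ_n − θ_p)`, their leading eigenvectors under a
   majority-non-negative sign convention, in-/antiphase magnetization,
   cosine-distance k-means mode extraction with silhouette model selection,
   mode connectivity/connectogram edge lists, regional contributions.
3. **metrics** — per-community Kuramoto order, META (temporal SD of the
   order parameter), chimerality CHI, the phase-locking variance proxy VAR,
   global integration (threshold-integral of the largest-component
   fraction), functional segregation (Louvain/Newman modularity) and the
   metastability index K = FSEG/GINT.
4. **stats** — ICC(1,1) run reliability, aligned-rank-transform mixed 2×R
   ANOVA, Friedman/Wilcoxon tests with rank effect sizes, permutation Welch
   t-tests, Bonferroni correction, assumption checks, and a seven-step
   decision flowchart for group × run designs.
5. **classify** — single-feature Gaussian naive Bayes with class balancing,
   repeated stratified k-fold cross-validation, out-of-sample transfer and
   binomial significance (case class positive).
6. **synthetic** — a multi-oscillator coordination model with first- and
   second-order coupling (`B = b·A`; Kuramoto when `b = 0`, stable
   antiphase coordination when `b > 0`), exponential-dwell template
   switching, cohort-level coupling perturbations, and plain-text fixtures.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (boundary values,
potential-landscape checks, oracle equivalences, statistical calibration,
planted-structure recovery, determinism); the calibration and power tests
take a few minutes.

## CLI

```sh
# simulate a small two-cohort dataset and write it as a TSV fixture
dfcmeta simulate --n-regions 30 --n-subjects 10 --n-frames 150 \
    --case-scale 0.5 --seed 1 --out data/

# full analysis: preprocess -> modes -> metrics -> stats -> classify
dfcmeta pipeline data/manifest.csv --k-range 2:10 --kmeans-reps 300 \
    --n-perm 9999 --cv-folds 10 --cv-reps 20 --balance down \
    --seed 1 --out results/run1

# individual stages
dfcmeta preprocess data/manifest.csv --band 0.01:0.08 --out results/prep
dfcmeta modes data/manifest.csv --fixed-k 5 --out results/modes
dfcmeta metrics data/manifest.csv --fixed-k 5 --out results/metrics.csv
dfcmeta stats results/metrics.csv --metric global_var --out results/stats.json
dfcmeta classify results/metrics.csv --feature global_var --out results/clf.json
```

Mode extraction is always per dataset (one group × run at a time); modes
are never fitted across groups, so no group structure leaks into the
dimensionality reduction.

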