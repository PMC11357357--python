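# hippostress

A tested re-implementation of a longitudinal mental-training analysis
pipeline linking hippocampal subfield volume and seed functional
connectivity changes to diurnal and hair cortisol changes — exercised end to
end on a synthetic cohort generator with known ground truth, so every stage
is verifiable by parameter recovery without access to the original cohort.

## What it does

- **`hippostress.synth`** — simulates a four-cohort (TC1/TC2/TC3/RCC),
  four-timepoint (T0–T3) design: subfield volumes with module-specific
  standardized change effects, two-day diurnal saliva profiles, hair
  steroid segments, resting-state parcel/seed time series with planted
  connectivity networks, and head motion. A shared latent factor couples
  CA1-3 volume change to diurnal cortisol output change at a configurable
  correlation.
- **`hippostress.cortisol`** — log transform, 3-SD winsorization (per
  occasion across the full sample), two-day averaging, then CAR
  (individual-peak rule with inverse-CAR fallback), diurnal slope
  (awakening → 600 min), and AUCg (trapezoid over the 0/240/360/480/600-min
  samples; 30/60-min samples excluded); hair change scores per 3-month
  segment.
- **`hippostress.connectivity`** — Power framewise displacement, ±1-frame
  scrubbing at FD ≥ 0.5 mm, mean-FD > 0.3 mm scan exclusion, seed–parcel
  Pearson r → Fisher z → per-profile 0–1 rescale, frozen baseline top-10%
  ipsilateral networks (20 of 200 parcels), network-mean FC and per-parcel
  change tables.
- **`hippostress.contrasts`** — module-labelled change records, mixed-model
  (random subject intercept) or OLS Wald contrasts with age/sex covariates,
  Cohen's D, BH-FDR / Bonferroni correction, and change–change
  associations.
- **`hippostress.pls`** — behavioral PLS: subject/age/sex residualization,
  within-group normalization, cross-covariance SVD, permutation
  significance (row-, group-, or subject-block-wise) with FDR, bootstrap
  percentile CIs of loading correlations, per-group latent score
  expression.
- **`hippostress.pipeline`** — one-seed reproducible orchestration with
  per-stage record accounting and a deterministic `report.json`.

## CLI

```sh
hippostress simulate --seed 1 --out data/                 # synthetic cohort
hippostress cortisol --saliva data/saliva.tsv --hair data/hair.tsv \
    --out out/cortisol_indices.tsv
hippostress connectivity --fmri-dir data/fmri --out-dir out/
hippostress contrast --changes out/changes.tsv --contrast Affect,Perspective \
    --family volume --out out/contrasts.tsv
hippostress associate --changes out/changes.tsv --brain volume:R_CA1-3 \
    --cortisol cortisol:AUCg --out out/assoc.tsv
hippostress pls --changes out/changes.tsv --model ca13 --out-dir out/pls
hippostress run --config run.yaml          # full pipeline, writes report.json
```

A run config is a YAML mirror of `hippostress.pipeline.RunConfig`; the
effective config is echoed into the output directory and hashed into the
report.

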