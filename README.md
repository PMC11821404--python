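# synofab

Paired plasma / synovial-fluid (SF) comparison for rheumatoid-arthritis
cohorts: clonal IgG1 Fab repertoire profiling from intact-mass LC–MS
deconvolution output, and bulk-proteome label-free quantification (LFQ)
analysis — with a synthetic paired-fluid cohort generator so every stage can
be validated by parameter recovery.

## The scientific problem

How freely do plasma proteins — including individual antibody clones and
systemically administered therapeutic mAbs — pass from blood into the
synovial fluid of inflamed joints? The package implements a three-tier
analysis of paired plasma/SF samples:

1. **Fab profiling.** IgG1-specific hinge cleavage releases ~48 kDa Fab
   fragments; each antibody clone appears in intact-mass LC–MS as a unique
   *(mass, retention time)* pair. Starting from per-run deconvolution
   component tables, the pipeline filters credible Fab species
   (45.0–56.2 kDa, top charge state above 1000 *m/z*, deconvolution score
   ≥ 40), calibrates matching windows as **3× the standard deviation** of the
   spiked standard mAbs (trastuzumab + alemtuzumab, 1:1), clusters components
   across samples into clones (greedy intensity-ordered centroid clustering),
   and converts intensities to concentration:

   `conc [µg/ml] = (I_clone / mean(I_standards)) · spike_ng_per_mab / volume_ml / 1000`

2. **Repertoire statistics.** Pairwise overlap percentages, Pearson
   correlation matrices of log10 clone concentrations (absences imputed at
   0.01 µg/ml), OLS regression of log10 SF concentration on log10 plasma
   concentration per patient, top-10 clone contributions, and
   concentration-weighted mass profiles. Therapeutic mAbs (e.g. adalimumab)
   are traced by their distinctive mass and retention time.

3. **Proteome comparison.** A genes × samples MaxLFQ table is filtered
   (unique peptides in ≥ 6 of 9 samples of either fluid; immunoglobulin
   variable-domain entries removed; LFQ must exceed 5·10⁵), missing values
   are imputed with the lowest observed LFQ, proteins are assigned to seven
   categories (plasma, cartilage, neutrophil, erythrocyte, platelet, generic
   cell, noncategorized), and plasma-vs-SF Pearson correlations are computed
   — patient-averaged, per patient, and stratified by molecular weight
   (40–100, 110–500, 510–1000 kDa, using assembly masses for multimers).

The synthetic generator (`synofab.synthetic_data`) emulates the study regime
— ~140–450 clones per sample with log-normal concentrations spanning
0.1 to beyond 100 µg/ml, ~90 % clone sharing between a patient's fluids and
none between patients, Gaussian mass/RT measurement noise, two spiked
standards per sample, and paired LFQ tables with SF-only protein classes —
and records the full ground truth.

## Worked example

```python
import synofab as sf
from synofab.pipeline import run_fab_pipeline
from synofab.cli import DEFAULT_STANDARDS

cfg = sf.CohortConfig(n_patients=2, clones_per_sample_range=(140, 200), seed=42)
cohort = sf.generate_cohort(cfg)
res = run_fab_pipeline(cohort.components, cohort.sample_meta, DEFAULT_STANDARDS)
print(res.overlap.round(1))
for p, fit in res.regressions.items():
    print(p, f"R2={fit.r2:.2f} slope={fit.slope:.2f} p={fit.pvalue:.2g} n={fit.n}")
```

prints

```
            P01_plasma  P01_SF  P02_plasma  P02_SF
P01_plasma       100.0    90.3         0.7     0.7
P01_SF            90.3   100.0         0.0     0.7
P02_plasma         0.5     0.0       100.0    92.0
P02_SF             0.5     0.5        92.5   100.0
P01 R2=0.52 slope=0.74 p=1.3e-26 n=158
P02 R2=0.41 slope=0.64 p=8.9e-25 n=201
```

Each patient's plasma and SF repertoires overlap by ~90 % (the generator's
within-patient sharing), repertoires of different patients barely at all, and
the paired log-concentration regression is highly significant within each
patient — the block pattern the method is designed to expose. The same flow
is available from the shell:

```bash
synofab simulate --seed 42 --out cohort/
synofab fabprofile --components cohort/ --sample-meta cohort/sample_meta.json --out fab/
synofab proteome --lfq cohort/lfq.tsv --sample-meta cohort/sample_meta.json --out prot/
```

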