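# Methods

## Clone definition and the matching windows

A clone is an IgG1 Fab species identified by its neutral mass and LC
retention time. Deconvolution components are accepted as Fab fragments when
45.0 kDa ≤ mass ≤ 56.2 kDa, the most intense charge state exceeds 1000 m/z
and the deconvolution score is ≥ 40; component masses backed by a subspecies
peak list are first re-estimated as the intensity-weighted mean over the
smallest intensity-descending prefix of peaks reaching 90 % of the summed
intensity (suppressing adduct/satellite tails). When no peak list is present
the exported mass is used as-is, since vendor exports may be pre-aggregated.

Matching windows are k·σ with k = 3, where σ_mass and σ_rt are pooled sample
standard deviations of the spiked standard mAbs observed across runs
(variance pooled by degrees of freedom). Calibration uses only the two
standards by default because they are present in every run and cannot be
confused with endogenous clones; `estimate_tolerances(extra_observations=…)`
optionally pools additional recurring high-intensity clones. Windows are
bounded below by floors (0.5 Da, 0.05 min) so that a degenerate zero-variance
calibration — e.g. noise-free synthetic data — never yields zero-width
windows; degenerate calibration raises a warning and is flagged on the
returned model.

## Clustering

Cross-sample clone formation is greedy intensity-ordered centroid
clustering: components are processed in descending intensity (ties broken by
ascending mass, making the pass fully deterministic); each component joins
the existing clone whose intensity-weighted consensus (mass, RT) lies within
both windows and that has no member from the component's sample — ties
broken by smallest |Δmass|, then |Δrt| — or founds a new clone. The
consensus is recomputed on every join. The intensity ordering anchors
centroids on the strongest, most mass-accurate species; an updating centroid
was chosen over matching against a fixed first-seen position, and greedy
assignment over single-linkage components because single linkage chains
beyond the window. Mass windows are absolute Daltons (not ppm), consistent
with their SD-based definition. Within-run duplicates are merged first under
the same windows with intensities summed, so total intensity is conserved.

A structural property of k = 3 windows worth knowing: two observations of
the same clone differ by N(0, σ√2) per dimension, so the probability that
the second observation falls inside the window around the first is
P(|Z| ≤ 3/√2)² ≈ 93 % regardless of σ. A few percent of genuinely shared
clones therefore appear as two single-fluid entries ("self-splits"). This is
inherent to the 3-SD rule, mirrors the unique-to-one-fluid clones seen in
real repertoires, and is why the paired-regression recovery analysis is
evaluated against ground-truth clone identity (below).

## Quantification

Per sample, the two standard intensities are combined as an arithmetic mean
(a geometric-mean option exists but is off by default), and

conc [µg/ml] = (I / mean(I_std)) · spike_ng_per_mab / volume_ml / 1000.

spike_ng_per_mab is half the total spike of the 1:1 two-mAb mix (200 ng for
a 400 ng total-IgG1 spike; 50 ng for a 100 ng ACPA-tier spike): the
normalization target is the per-mAb average intensity, so the matching
amount is per mAb. Standards are identified after cross-sample clustering so
that the standard clones also exercise the tolerance model; matching is per
sample (nearest in-window member, at most one clone per standard per
sample), and all clones that answered for a standard are removed from the
repertoire. A sample in which a standard is missing is flagged and excluded
from quantification rather than imputed — quantification without its anchor
is undefined. Global intensity scaling cancels (clone and standard scale
together) and halving the applied volume doubles reported concentrations.

## Repertoire statistics

Overlap(A,B) = 100 · |clones of A matched in B| / |A|, count-based and
asymmetric since |A| ≠ |B| in general; an intensity-weighted variant is
available behind a flag. Correlation matrices and the paired regression use
log10 concentrations over the union of each pair's clones with absences
imputed at 0.01 µg/ml (one decade below the practical detection floor);
pairs with fewer than 3 union clones are reported missing. The regression is
ordinary least squares of log10 SF on log10 plasma concentration with the
standard t-test p-value on the slope; no multiple-testing correction is
applied because regressions are reported per patient, not screened. Pearson
on log10 equals Pearson on natural log; log10 is fixed for reproducibility.
Top-contribution summaries break concentration ties toward the lower
consensus mass; mass profiles use half-open [lo, hi) bins so an edge mass
counts once.

## Proteome analysis

The detection filter keeps genes with unique peptides in ≥ 6 of 9 samples of
the plasma group OR of the SF group (parameterized for other cohort sizes);
the per-fluid OR keeps fluid-specific proteins. Missing LFQ values are then
imputed with the table-wide minimum observed LFQ (a single detection floor,
not per-gene), and the correlation filter removes immunoglobulin
variable-domain entries (they are antibody clones, handled by the Fab tier)
and genes never exceeding 5·10⁵. Correlations are computed on log10
abundances (linear-space Pearson available behind a flag): averaged mode
correlates per-gene means over the plasma samples against means over the SF
samples; per-patient mode correlates each patient's paired samples. The
size-stratified analysis assigns annotated genes to 40–100 / 110–500 /
510–1000 kDa strata by assembly mass (falling back to monomer mass); genes
between strata are excluded and listed; strata with < 3 genes report NaN.
The packaged 19-gene annotation file holds rounded literature/UniProt
masses and is editable.

## Synthetic cohort generator

Defaults encode the study regime: 9 patients, per-sample clone counts
uniform in [140, 450], within-patient sharing 0.9 (a binomial share of each
patient's clones is present in both fluids with one shared true
concentration), between-patient sharing 0, log10 concentrations
N(0.3, 1.0²) in µg/ml (heavy-tailed clone abundances spanning ~3 decades,
with the occasional clone beyond 100 µg/ml), clone masses uniform in
46–51 kDa and RTs uniform over a 12–40 min window (clone RT distribution is
not constrained by the measurement physics; uniform over the gradient window
is assumed), Gaussian measurement noise σ_mass = 1.5 Da and
σ_rt = 0.05 min (conservative run-to-run reproducibility for recalculated
intact-Fab masses at this resolution, and half the upstream 0.1-min
RT-window quantization), and unit-mean log-normal intensity noise with
CV 0.2 (clones) and 0.05 (standards — the spikes are clean by design, and
they anchor both calibration and quantification). Emitted intensity is the
exact inverse of the quantification formula, so recovered concentration
equals truth up to the intensity noise and the standards' mean. Plasma and
SF applied volumes default to 0.01 and 0.05 ml (volumes containing ~50 µg
IgG1 at typical fluid concentrations). The LFQ table draws gene-level log10
abundances N(7, 1²) — four orders of magnitude — adds independent per-sample
noise of configurable SD, and leaves cartilage/neutrophil/generic-cell
genes structurally missing in plasma; a missing-at-random dropout rate
(default 5 %) applies on top.

Two closed-form calibration helpers invert the noise model:
`intensity_cv_for_target_log_r` gives the intensity CV whose true paired
log-concentration Pearson is a prescribed ρ (shared clones carry one true
concentration and independent per-fluid noise, so ρ = s²/(s²+σ_log²)), and
`proteome_noise_sd_for_target_r` the per-sample LFQ noise for a prescribed
true correlation of a given estimand (averaged over n samples the noise
variance entering the correlation is σ²/n).

## What the recovery analyses show — and what they do not

Parameter-recovery analyses run at: 9 patients × 300 clones/sample with
intensity CV 0.05 for concentration recovery (median relative error and a
traced therapeutic injected at its literature plasma level, 9.0 µg/ml, with
a distinctive RT outside the clone window); 20 replicates of a 300-clone
fully-shared patient at the CV whose true paired log-correlation² is 0.75
for regression recovery; 4 patients × 140–200 clones for the
within/between-patient block pattern; and 200 replicates of 300 plasma
genes (+ 3×20 SF-only genes) for the proteome correlation and category-sign
analyses. Sizes were chosen so the whole suite runs in seconds on one core
while keeping sampling error well inside the assertion bands.

The regression-recovery replicates resolve clone identity through the
generator's ground-truth uids (`ground_truth_repertoires`): they validate
generation + quantification + regression. The full-chain R² (window
matching included) is systematically lower because each self-split clone
contributes an imputed 0.01 µg/ml point on one side (see the 93 % note
above); the acceptance report includes that number separately. Passing
recovery on synthetic data shows the estimators are unbiased under the
generator's assumptions — independent Gaussian/log-normal noise, no RT
drift, no co-eluting isobaric clones, no intensity-dependent mass error, no
glycoform microheterogeneity — not that real repertoires meet those
assumptions.

## Degenerate inputs and conventions

Empty component tables yield empty catalogs and a warning, not an error.
Empty repertoires make overlap/correlation entries missing (NaN), never 0.
Constant vectors are rejected by min–max normalization and by the regression
when the predictor is constant after imputation. All-missing LFQ tables
cannot be imputed. Configuration errors name the offending field. Fixed
seeds give byte-identical generator output; pipeline results are
deterministic given inputs (explicit sort keys everywhere a tie could occur).

## Known limitations

Charge-state deconvolution is consumed, not modeled: generation starts at
the component-table level, with no spectra, envelopes or peak shapes. The
Fab tier assumes the IgG1-only digestion chemistry (no isotype inference).
MaxLFQ is consumed as produced upstream; no peptide-level inference or FDR
machinery. Whether the original analysis matched to fixed or updating
centroids, and whether its overlap percentage was count- or
intensity-weighted, is not documented; the choices here (updating centroid,
count-based) are stated as this package's conventions, with the
intensity-weighted overlap behind a flag.
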