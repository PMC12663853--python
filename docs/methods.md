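# Methods

## Activity quantification

A well's readout is an acidification-rate (AR, mpH/min) series split
positionally into four injection phases (baseline, rotenone/antimycin A,
ATP+FCCP, oligomycin), three measurements per phase by default. Phases are
assigned from the injection schedule by position, never by timestamps;
measurement indices are 1-based in files and 0-based internally. Per-well
activity is the arithmetic mean of the ATP+FCCP phase minus the mean of
the oligomycin phase. Only these two phases enter the estimate; baseline
and rot/AA measurements are carried for inspection but no QC cutoff is
attached to them by default, and the package ships QC *flags* (negative
activity, missing replicate, non-finite measurements excluded) rather than
exclusion thresholds.

Technical replicates (triplicate wells per biological sample by design)
are combined by the arithmetic mean of well activities; with balanced
phases this equals differencing the pooled phase means, and it is the
simplest estimator consistent with the activity formula. Negative
activities are retained and flagged — truncating at zero would bias group
means upward. Non-finite AR values are excluded from phase means, never
imputed; a fully unusable well propagates as a missing replicate, and a
sample with no usable wells is dropped with a logged warning.

## Mitochondrial-content normalization

Relative mitochondrial content is the duplicate-mean MTDR fluorescence
minus the plate blank, where the blank is the mean over all blank (dye +
buffer) wells on the plate — averaging all blanks minimizes blank noise.
Normalized activity is raw activity divided by this net signal (mpH/min
per fluorescence unit). All samples of a tissue are assumed measured on
one plate at a fixed gain, so net MTDR values are comparable within
tissue; cross-tissue comparisons use the normalized activity as-is, which
is an assumption inherited from the assay design. A sample whose net
fluorescence is ≤ 0 has no physically meaningful ratio and is excluded
with reason `nonpositive_content` instead of producing signed infinities.
Protein loading is equalized per tissue by the assay configuration
(per-tissue µg/well table), so no additional per-protein normalization is
applied.

## Contrast statistics

Per tissue, the four group comparisons (OM–YM, OF–YF, YM–YF, OM–OF) use a
two-sided Welch unequal-variance t-test on per-animal normalized
activities. Two points deserve emphasis: the test family is a documented
choice (a letter-tier presentation does not pin down the underlying test),
and **no multiple-testing correction is applied to the activity atlas** —
tiers are raw-p bins with strict thresholds (a: p < 0.05, b: < 0.01,
c: < 0.001, d: < 0.0001; p = 0.05 exactly maps to no tier). Degenerate
input with zero variance in both groups and equal means returns p = 1 by
convention. log₂ fold change requires both group means strictly positive;
otherwise the cell is undefined (NaN in tables) and Δ-based statistics,
which are always defined, carry the comparison.

Reproductive tissues (testes, fallopian tubes) exist in one sex and are
excluded from cross-sex contrasts. The cumulative |Δ| attribution of an
effect (age or sex) sums the absolute mean differences of the effect's two
contrasts per tissue and reports percent contributions (ascending); it
requires both contrasts, so reproductive tissues are excluded there for
the age effect as well, since each carries only one within-sex contrast.
Whether attribution should use raw or normalized activity is not forced by
the analysis; normalized activity is used, consistent with every other
panel.

The systems-level distribution comparison uses the two-sample
Kolmogorov–Smirnov test on the per-tissue group-mean vectors; the
"distributions do not differ" claim is only as strong as the KS test's
sensitivity at n ≈ 32. PCA operates on the 4 group × tissue mean-profile
matrix; columns with missing cells (sex-specific tissues) are dropped,
then columns are centered and unit-scaled (population SD) — unit scaling
keeps high-activity tissues from dominating the embedding; this choice is
documented because an unscaled PCA is equally defensible.

Aging categories compare the signs of per-sex log₂(old/young): both above
ε → Increased, both below −ε → Decreased, strictly opposite → Divergent,
and a magnitude ≤ ε in either sex → NearZero, reported separately. The
default ε = 0 gives the strict trichotomy everywhere except exact zeros,
which a three-way sign split cannot classify; ε is configurable, and
recovery tests on zero-noise data use ε = 1e-9 purely to absorb float
round-off of true-zero fold changes.

Ranking ties are broken by tissue name for determinism.

## Expression panel analysis

The packaged 19-gene panel (F₁/F₀ subunits plus assembly factors, with
one-to-one human/mouse orthologs) ships as package data; no live ortholog
lookup is performed. Columns of the individuals × gene_tissue TPM matrix
are retained when TPM is strictly > 1 in at least 30% (inclusive) of
individuals. Age dichotomization: mouse young ⇔ age ≤ 15 months; human
old ⇔ age strictly > 50 years. The source protocol states the mouse
cutoff both as ">15 months old" and as "1.5 years"; the explicit ≤15/>15
rule is implemented and the cutoff is exposed as a parameter. "Two-way
t-tests" is read as two-sided two-sample t-tests (the phrase is
nonstandard). FDR adjustment defaults to Benjamini–Hochberg because it is
fully specified with no tuning parameter; a Storey q-value mode (spline
π₀ smoother, falling back to π₀ = 1 below 100 tests) is available, and the
results table records which method produced its q column. Adjustment is
applied across the columns of the panel that is passed in — the pipeline
calls it once per sex, i.e. q-values are controlled within sex across the
tissue set; within-tissue or global adjustment are alternative readings.

Activity–expression concordance maps expression tissue labels onto
activity tissue labels through an explicit, editable alias CSV (e.g.
SubQ/iWAT → iWAT); unmapped labels are reported indeterminate, never
guessed — bulk labels like "Heart" or "Kidney" are deliberately left
unmapped because the activity atlas resolves sub-structures (atrium vs
ventricle, cortex vs medulla). A tissue's expression direction is the
majority vote of its panel genes' signs (tie → indeterminate), and
concordant/discordant requires equal/opposite nonzero signs on both
sides.

## Synthetic-data generator

The generator emulates the statistical structure of the three raw input
kinds with additive Gaussian noise (no noise model is implied by the
assay; additive Gaussian is the neutral choice). Trace levels: baseline
`b`, rot/AA `b − d`, ATP+FCCP `b − d + a·c + r`, oligomycin `b − d + r`,
where `a` is true normalized activity, `c` true mitochondrial content and
`r` a non-Complex-V residual — so the well-activity difference recovers
`a·c` and MTDR normalization recovers `a` (to float round-off at zero
noise; exact equality of sums-of-means is not a float identity, and
recovery tests assert 1e-12 relative). Defaults: baseline 8 mpH/min, drop
3, residual 1, content lognormal around 1000 a.u. with 10% per-animal
spread, blank 500 a.u., 4 blank wells. Noise can be absolute
(`noise_sd_ar`) or proportional to the well's true signal (`noise_cv_ar`);
fluorescence noise is absolute and values are emitted as drawn (no
clamping), so heavy noise exercises the nonpositive-content exclusion.

The default ground-truth activity table is **illustrative, not data**: its
levels put contractile organs high and gut/skin/fat low, and its effect
directions follow the qualitative atlas patterns — male age increases in
heart atrium/diaphragm/cecum/ileum/gWAT and decreases in
tongue/gastrocnemius/kidney cortex; female age decreases in fat
depots/liver/spleen/distal colon/skin/fallopian tubes and increases in
diaphragm/ileum; young-female elevations in skin/gWAT/pancreas/heart
atrium/spleen; plus a block of shared (both-sex) moderate age declines and
two shared increases so that age touches clearly more tissues than sex.
Base values are chosen pairwise distinct within every group so true
rankings are well-defined. The expression generator draws log-normal TPM
(log₂ TPM ~ Normal, σ = 0.5 by default) with a configurable non-null
column fraction and effect size, and returns truth labels.

What passing synthetic tests does *not* show about real data: real plate
noise is heteroscedastic and temporally correlated within a well, real
MTDR blanks can drift within a plate, tissue activities are not constant
within a group (no biological between-animal variance is placed on `a`
beyond content variation), and TPM distributions are heavier-tailed than
log-normal. The generator validates the pipeline's arithmetic, calibration
and power properties, not the biology.

## Problem sizes and numerical choices

Recovery and calibration suites use a full-design atlas (33 tissue labels,
n = 10/group, triplicate wells, ≈ 3840 traces), a 1000-tissue null
simulation for tier calibration, 1000 × 200-column null replicates for FDR
calibration, and 500 random instances for attribution conservation; unit
tests use 2–8-tissue designs. Output tables pin column order and use
12-significant-digit float formatting so re-runs are byte-identical;
plate/MTDR/expression CSVs are written at 17 significant digits and read
with exact-rounding float parsing, making file round-trips bit-exact. All
random streams are `numpy.random.default_rng` seeded from a single run
seed; the MTDR stream uses a fixed offset of the plate seed so the two
stages do not alias.

## Known limitations

- The activity atlas reports raw-p tiers; with ~130 contrasts some tier-a
  calls are expected under the null.
- MTDR is a relative, dye-based content proxy; no absolute mitochondrial
  quantification is modeled.
- Only the hydrolytic (reverse) mode is modeled; forward-mode ATP
  synthesis and its coupling to membrane potential are out of scope.
- The design is cross-sectional with two ages; no longitudinal or
  mixed-effects modeling is attempted.
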