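# Methods

## Quantification model

Competitive internal-standard qPCR measures each native template (NT) against
a known number of synthetic internal-standard (IS) molecules sharing its
primer sites and co-amplified in the same well on a second fluorescence
channel. Under the core assumption — identical per-cycle efficiency for NT
and IS — the NT:IS copy ratio is invariant through amplification, dilution
and interference, so

    NT copies = IS copies × 2^(−corrected ΔCq),
    corrected ΔCq = (Cq_NT − Cq_IS) − mean ΔCq of external-standard wells.

The external-standards mixture (ESM) is a 1:1 NT/IS mixture of every assay
gene run at two working concentrations (10⁻¹³ and 10⁻¹⁴ M) in each
experiment. Its expected ΔCq is zero; the measured mean absorbs channel
intensity and threshold-selection drift. The offset is averaged in ΔCq (log)
space per run and gene — averaging linear-scale ratios would weight the two
calibrator levels unequally and is rejected. Per-run offsets are the
default; a pooled mode exists for designs with shared calibration.

Target genes are reported per 10⁶ reference-gene (default ACTB) molecules,
each PCR reaction normalized against its own reaction's reference
measurement. Replicate aggregation (mean, n−1 SD, CV) happens after
normalization.

### Gating and call logic

Reporting is restricted to a 10-fold NT:IS imbalance (|corrected ΔCq| ≤
log₂ 10, boundaries inclusive), because linearity degrades outside that
window. Gated-out wells keep their computed value in the per-well table for
audit but are excluded from clinical summaries. Call logic is fail-safe by
construction: NT and IS both detected → quantifiable; NT undetermined with
IS detected → target not detected (a reportable true negative, normalized
value 0); IS undetermined → assay failed, a no-call that is never converted
to a number. A sample whose reference gene is not quantifiable in a run
yields no normalized values for that run.

Undetermined Cq is an explicit sentinel (empty CSV field or the literal
`UNDETERMINED`; NaN in memory), never a magic cycle number. All rounding
(1–2 significant figures, matching how such assays are reported) is a
presentation option; internal arithmetic is full precision. Copy numbers
derive from molarity with Avogadro's constant fixed at 6.02214 × 10²³; the
nominal "600000 / 6000 molecules" labels of the mixtures are the
1-significant-figure roundings of the exact products.

### Standards mixtures

Internal-standard mixtures (ISM) A–F pair one reference-gene concentration
with one concentration for all target genes. Only two compositions are fixed
by the published protocol (D: 10⁻¹² M reference / 10⁻¹⁴ M targets; E:
10⁻¹²/10⁻¹⁵); published sources disagree on the letter assignments of the
others, so the catalog is config-driven, the remaining letters ship as
illustrative values spanning the working range, and any real mixture lot
should be declared in run config. `select_ism` chooses the catalog entry
closest to an expected abundance on a log scale (first entry wins ties) and
flags when no entry can bring the ratio inside the gate.

## Limiting-dilution statistics

At limiting dilution the molecules captured by a well are Poisson, so the
probability of any detectable product is 1 − e^(−λ). The accuracy check
regresses observed positive fractions on these expectations (unweighted OLS;
the published analysis gives no weighting, and saturated endpoints are
included by default). The MPN estimator maximizes the binomial likelihood
Σ k·log(1 − e^(−c·v·d)) − (n−k)·c·v·d over c > 0 via a bracketed root of the
score; the 95% interval is the profile likelihood at a drop of 1.92
(χ²₁/2), chosen over Fisher-information intervals because 9 replicates per
level are too few for the quadratic approximation. All-negative series
return 0 with an upper bound; all-positive series return a lower bound only
and a flag. The estimate is reported on the scale of the top dilution level.

## Diagnostic index

The LCDT index is (MYC × E2F1) / CDKN1A on per-10⁶-ACTB values; the form is
stored as a config expression so it is visible and overridable. Verified
against all 20 bundled reference samples: every row agrees within the bound
set by the published inputs' 2-significant-figure rounding (< 8% compound
deviation), and half the rows, including the SB1 spot check, match the
printed index exactly at 2 significant figures. Higher index ⇒ malignant is
fixed by the class means, not auto-detected.

AUC is the tie-adjusted Mann–Whitney statistic (midranks; identical to
half-weighted pair counting), with a Hanley–McNeil normal-approximation CI
reported unclipped — at n = 10 + 10 it can exceed 1, as in the source
study's 0.82–1.04. The operating cutoff maximizes Youden's J over midpoints
between adjacent sorted values plus ±∞ sentinels (standard empirical-ROC
practice); J-ties resolve to the higher-specificity cutoff. Group comparison
uses Levene's test (mean-centred) to route between pooled and Welch t-tests;
because the index is ratio-scaled, a log₁₀ option is provided — the published
p-value's transform is unstated, so both are first-class.

## Simulator

The simulator is mechanistic but deliberately minimal; its purpose is to
generate wells tables with known ground truth that exercise every failure
mode the pipeline guards against.

- **Amplification.** Every template in a well grows per cycle by
  e_c = e0 · h(dose) · max(0, 1 − total/capacity), identical across
  templates. Defaults: e0 = 0.95; capacity 10¹¹ copies, a single shared
  reagent pool per well (the simplest mechanism that reproduces late-cycle
  Cq compression; per-gene capacities were rejected as adding parameters
  without changing any tested behaviour).
- **Workflow.** 18-cycle multiplex pre-amplification of all genes plus the
  ISM, net 20000-fold material reduction between rounds (a 1000-fold
  dilution of which 1/20 of a reaction volume is carried forward), 40-cycle
  per-gene second round. The published ~9–10-cycle net Cq gain from
  pre-amplification is not a calibration target — it depends on unreported
  carryover volumes — so the dilution factor is exposed instead.
- **Detection.** Channel fluorescence = copies × per-channel scale ×
  per-run lognormal drift (sd 0.1 by default). The threshold defaults to
  10⁻³ of capacity-equivalent fluorescence; a `baseline_sd` mode adds
  per-run lognormal threshold drift emulating auto-threshold variation.
  Cq is the log-linear interpolated crossing cycle, or undetermined within
  the cycle budget. Per-well Gaussian Cq jitter, sd 0.1 cycles.
- **Inhibition.** A Hill dose-response h(d) = 1/(1 + (d/3.0 mM)⁸) scales
  efficiency — an explicit modelling invention calibrated qualitatively to
  signal loss near 4 mM EDTA, config-exposed.
- **Randomness.** One root seed; every reaction and well derives its
  substream from a stable CRC-based hash of (seed, plate, well), so outputs
  are byte-identical per seed and any well is reproducible in isolation.

### Known second-order bias (documented, not hidden)

The 2^(−ΔCq) readout assumes doubling. With per-cycle growth 1 + e < 2, a
true NT:IS ratio R is read out as R^(ln 2 / ln(1+e)) (≈ R^1.04 at e = 0.95):
exact at R = 1, a few percent at the gate edges, and larger under strong
inhibition (growth 1.77 at 3 mM gives ≈ R^1.21). This is a real property of
ΔCq-based competitive quantification, consistent with the slight slope
deviations published for non-1:1 dilution series; it is why the
dose-invariance and exact-recovery tests pin the ratio at 1:1 and why the
ideal-doubling configuration (e0 = 1, threshold far below saturation) is
used for identities that hold only exactly there.

### Cohort generator

Benign/malignant samples draw per-gene expression (per 10⁶ ACTB) from class
lognormals with the bundled reference cohort's class averages as default
medians and geometric SD 1.5; absolute ACTB input is lognormal (median
7 × 10⁵ molecules/reaction, gsd 1.5 — cDNA loading is normalized upstream by
RNA input, so the spread is modest, and the median sits at the geometric
balance point where one ISM covers all three targets). Each sample is
assayed in triplicate runs, each run with its own calibrators, drift and
threshold. Samples whose drawn expression pushes a gene outside the 10-fold
gate lose that gene from clinical summaries — faithful to the method, which
would re-assay such samples with a different ISM; the generator does not
model that titration loop.

### What the simulator does not model

No sequence-level effects (primer thermodynamics, probe hybridization,
cross-hybridization), no reverse-transcription step or RNA fragmentation, no
raw fluorescence curve shapes of real instruments, no inter-well
cross-contamination. Passing tests therefore demonstrate the correctness and
fail-safety of the calculation and calling machinery under the stated
mechanism, not the wet-lab performance of any particular reagent set;
probe-specific cross-reactivity rates and experimental CV tables are
inherently instrument data.

## Problem sizes and numerical choices

Test and acceptance computations use desk-scale sizes chosen to make each
check statistically decisive: 7-level dilution series in triplicate; 500
simulated series for the MPN median-recovery check and 500 random instances
for the AUC rank-vs-pair-count identity; 200 seeds for the accuracy-curve
Monte-Carlo cross-check (frozen independent-OLS mean r² 0.9156); 400 wells
for the Poisson detection-fraction link. MPN root-finding uses bracketed
Brent iterations in log-concentration with the estimator verified against a
dense grid search to 0.1%. Boundary comparisons (gate, cross-reactivity
threshold) are inclusive with a 10⁻¹² relative guard so exact boundary
values pass deterministically.

## Known limitations

- The ESM offset corrects channel-multiplicative and threshold drift; it
  cannot correct the e < 1 readout bias above, which is shared by the
  measurement model itself.
- The bundled reference tables are published roundings (Cq to one decimal,
  quantities to two significant figures); recomputations therefore match
  exactly where the rounding supports it and to within ~10% elsewhere, and
  tests assert at those documented precisions.
- The MPN model assumes perfect single-molecule detection after
  pre-amplification (a positive well is any determined Cq); detection
  failures below that ideal would bias concentrations downward.
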