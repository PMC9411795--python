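# Methods

`fishmet` models a multidimensional metabolomics study of drug
biodistribution and pharmacodynamics in adult zebrafish: absolute
quantitation of hydroxychloroquine (HCQ) across organs and serum,
whole-body DESI ion imaging, ¹³C₆-glucose isotope tracing of
N-acetylaspartate (NAA) biosynthesis in brain, and untargeted differential
metabolomics per organ. Every stage can run on synthetic data with known
ground truth, so the statistical behavior of the full pipeline is testable
end to end.

## Absolute quantitation

Quantitation is internal-standard based: a deuterated analog of the drug is
spiked at a fixed 1 µg/ml into every extract, and the analyte/IS peak-area
ratio is regressed on nominal concentration over a five-level 1:10 series
(0.01–100 µg/ml in extract). Because analyte and internal standard
experience the same matrix-dependent ionization suppression, the response
ratio is matrix-invariant to first order — which is why a single pooled
tissue curve can replace seven organ-specific curves (15 instead of 105
injections).

`fit_calibration` reports slope, intercept, R², Pearson r, and per-level
back-calculated accuracy and RSD. Two weightings are available:

- **`ols`** (default): unweighted least squares, the convention behind the
  reported curve statistics (R², r).
- **`1/x2`**: inverse-squared-concentration weights. Over a four-decade
  series with proportional (CV-type) noise, the absolute residuals at the
  top calibrator are ~10⁴ times those at the bottom, so an unweighted fit
  effectively fits only the 100 µg/ml level and its noise leaks into the
  intercept (±0.3 ratio units at CV 5%), corrupting back-calculation below
  ~1 µg/ml. The pipeline therefore quantifies samples with the weighted
  fit; this is standard bioanalytical practice for wide calibration ranges.

Unit conversion is fixed by the extraction protocol: tissues are extracted
at 40 µl solvent per mg, so µg/mg tissue = µg/ml extract × 0.04 ml/mg;
serum is diluted 1:15 at extraction, so µg/ml serum = µg/ml extract × 15.
Out-of-range samples are flagged against the calibrator span, never
suppressed or extrapolation-trimmed.

Group statistics follow the study conventions: two-tailed unpaired t-tests
for two-group comparisons (including the pooled-vs-specific strategy
comparison, where a paired design would be more powerful but the unpaired
test matches the protocol), and one-way ANOVA with Tukey's HSD at 95%
family confidence across organs. Steady state between 24 h and 48 h of
exposure is declared per organ when the unpaired t-test does not reject at
α = 0.05, with concentrations expressed relative to the liver 24 h mean.

## Isotope tracing and the NAA route model

NAA (6 carbons) is synthesized by condensing acetyl-CoA (2C) with aspartate
(4C). With ¹³C₆-glucose as tracer, three labeling routes are modeled:

1. **Direct acetyl route** — glucose → ¹³C₂-acetyl-CoA used as the acetyl
   donor: NAA M+2 from the acetyl moiety. Parameter `acetyl_labeled`
   (c₂), the M+2 fraction of the acetyl-CoA pool.
2. **Oxidative TCA route** — ¹³C₂-acetyl-CoA enters the TCA cycle; one
   oxidative turn yields M+2 oxaloacetate ⇌ M+2 aspartate. Parameter
   `asp_m2`.
3. **Pyruvate-carboxylase (PC) route** — ¹³C₃-pyruvate is carboxylated to
   oxaloacetate, transferring all three labeled carbons: M+3 aspartate and
   hence M+3 NAA. Parameter `asp_m3`. This is the anaplerotic route whose
   activity increases under drug treatment in the modeled study.

M+1 aspartate (attributed to malic enzyme) is a free parameter (`asp_m1`)
rather than a mechanistic output: only a single oxidative turn is modeled,
so multi-turn scrambling that could also produce M+1 is deliberately out of
scope. The CO₂ fixed by PC is assumed to come from an unlabeled bicarbonate
pool, so aspartate M+4 and NAA M+6 are unreachable in the model.

The NAA MID is the convolution of the acetyl MID `[1−c₂, 0, c₂]` with the
aspartate MID `[a₀, a₁, a₂, a₃, 0]`. Inference reads a₁–a₃ directly from
the corrected aspartate MID and estimates c₂ by least squares constrained
to [0, 1]; the model is linear in c₂, so the solution is a closed-form
projection. Without an aspartate MID the problem is not identifiable
(c₂·a₁ trades off against (1−c₂)·a₃); a bounded fit is still returned, but
flagged.

**Natural-abundance correction.** Observed intensities R relate to the
tracer-labeled distribution T through a lower-triangular matrix C with
C[j,i] = Binomial(n−i, p) evaluated at j−i, p = 0.0107 (¹³C only; ²H/¹⁵N/
¹⁸O corrections are out of scope). `correct_mid` solves C·T = R by
non-negative least squares, clips and renormalizes — plain inversion can
return negative fractions on noisy data. The forward convolution and the
NNLS inversion round-trip to < 1e-8 on random MIDs.

**Fractional labeling** divides each tissue isotopologue fraction by the
same animal's serum glucose M+6 fraction, normalizing out differences in
tracer uptake. Serum M+6 = 0 is an explicit error, not an infinity; a
cohort-mean fallback is not silently applied.

## Ion imaging

Images are regular rasters (150 µm pitch by default) of centroided channel
intensities. Processing steps: (1) lockmass recalibration — a constant ppm
shift inferred from a reference compound, rejected beyond 50 ppm;
(2) channel extraction within a ±10 ppm window (the identification
tolerance reused as a documented default — the imaging-specific window is
configurable); (3) per-pixel TIC normalization, where zero-TIC pixels (the
swim-bladder void in the synthetic fish) yield zeros and a flag count so
ROI statistics stay total; (4) ROI summaries (mean/median/max, ranked by
mean) over organ masks, which are inputs, never inferred. TIC normalization
is scale-invariant per pixel and commutes with single-channel extraction.
I/O: continuous-mode imzML via pyimzml plus an internal long-format TSV;
exports are 16-bit grayscale PNG with a numeric TSV companion.

## Untargeted analysis

Pipeline order is fixed: **blank filter → degeneracy collapse → annotation
→ differential statistics**.

- Blank filter: retain a feature iff mean(sample)/mean(blank) ≥ 3 (a
  conventional default — the study describes blank controls but states no
  cutoff); zero blank mean retains.
- Degeneracy collapse: features are linked when Δm/z matches a shift table
  (¹³C isotope +1.00336, Na−H +21.98194, K−H +37.95588, NH₄ +17.02655 Da)
  within 5 ppm, RT difference ≤ 0.2 min, and per-sample intensity
  correlation ≥ 0.8; links merge transitively and the most intense member
  represents the group. All three thresholds are declared defaults, not
  study facts.
- Annotation: level-1 identity requires accurate mass ≤ 10 ppm **and** RT
  within the window against a reference library; nearest mass wins ties.
- Differential: classic equal-variance two-tailed t-test per feature
  (Welch by flag), log2 fold change, and both raw and Benjamini–Hochberg
  adjusted p-values. Per-organ significant counts default to raw p < 0.05
  (the convention behind the altered-metabolite histogram); BH counts are
  always available as the conservative mode.
- Grubbs' outlier test: iterative two-sided, critical value from Student-t
  quantiles at α = 0.05; applied per organ per metabolite before group
  statistics. The single-outlier statistic is susceptible to masking when
  two comparable outliers coexist; this is inherent to the test, not
  worked around.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions, and every record it emits is traceable to a ground-truth entry.

- **Noise**: multiplicative log-normal with mean 1 and CV `noise_cv`
  (default 5%) — peak areas are positive with roughly proportional error.
  Feature tables use CV 20%, typical of untargeted intensities.
- **Design sizes**: 8 organs + serum; n = 8 fish for quantitation; n = 6
  control vs 9 treated for tracing; n = 6 vs 8 for feature tables —
  matching the modeled study's group sizes.
- **Biodistribution**: liver = intestine = 4× all other organs (the study
  reports >3×; 4 leaves headroom for noise). Suppression factors spread
  ±20% around 1; the pooled matrix is their mean.
- **Tracer**: serum glucose M+6 = 0.4, a realistic steady-state enrichment
  for waterborne ¹³C₆-glucose dosing (the study prints no value; this is a
  free parameter). Routes: control c₂ = 0.15, a₁ = 0.05, a₂ = 0.12,
  a₃ = 0.10; treated identical except a₃ = 0.15 (the 1.5× PC elevation the
  power analyses assume).
- **Images**: a fixed schematic organ layout (ellipses, not anatomically
  fitted) on a 40×80 grid at 150 µm; the swim bladder is a zero-intensity
  void; drug channels scale with biodistribution.
- **Features**: 120 endogenous features per organ of which an organ-specific
  subset (intestine 40 > muscle 30 > … > liver 8, free parameters mirroring
  the qualitative organ ranking) carries a 2× group effect in either
  direction; 30 contaminants present equally in blanks; ~30% of endogenous
  features carry one satellite at a shift-table mass with shared RT and
  correlated intensity. One blank per 10 samples. Tissue masses uniform
  2–20 mg; extraction fixed at 40 µl/mg.

What the generator does **not** emulate: chromatographic peak shapes and RT
drift, profile spectra, ion-mobility, inter-organ correlation of metabolite
levels, heavy-tailed biological variance, or missing values. Passing tests
therefore demonstrate the correctness and calibration of the computations
under the stated error model, not robustness to every artifact of real
LC/MS data.

Determinism: every stage derives an independent `numpy` generator from
(seed, stage-name hash), so identical configs give bit-identical outputs
and stages can be regenerated independently.

## Numerical choices and problem sizes

- MID validity tolerance 1e-9 on the unit sum; NNLS residuals reported, not
  hidden. Degenerate t-tests (zero variance, equal means) report p = 1.
- The workflow's per-group route inference averages corrected per-fish MIDs
  before inverting, trading per-fish diagnostics for stability at n ≤ 9.
- Simulation-based tests use modest replication (5–400 seeds depending on
  the statistic) chosen so the whole suite completes in well under a
  minute while keeping binomial confidence intervals comfortably inside
  the asserted bands; the problem sizes are stated in each test.

## Known limitations

- The route model is identifiable only with a companion aspartate MID.
- Single-turn TCA: no scrambling beyond the first oxidative turn.
- Pooled-vs-specific strategy comparison inherits calibration-slope noise;
  with many matrices an occasional sub-0.05 p-value arises from the curves
  alone, which is a property of the unpaired design, not a matrix effect.
- imzML support is limited to a shared (continuous-mode) m/z axis.
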