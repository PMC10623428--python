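# Methods

## Glucose-dynamics model

Tolerance-test curves are modelled as a damped harmonic oscillation
around a setpoint,

    G(t) = G0 + A · e^(−αt) · sin(2πt/T + φ),

the minimal form that generates the full derived parameter panel
(setpoint, amplitude decline, basic period, initial slope, extrema of
the curve and of its derivative, closed-form AUC).  The model treats
post-bolus glucose as a second-order regulated process returning to a
central setpoint; it does not model insulin–glucose coupling
mechanistically (no minimal-model analysis), and it assumes additive,
homoscedastic measurement noise on glucose.

Time is in hours everywhere internally.  Files store minutes, as
measured; the conversion happens once, at the I/O boundary.

### Fitting

Nonlinear least squares (trust-region reflective) with multi-start,
because the objective is multi-modal in (T, φ):

- `G0` start: mean of the last two points (the tail approaches the
  asymptote);
- `A` start: half the observed range;
- `T` candidates: 4·t at the largest excursion, plus {2, 3, 4, 6} h;
- `α` candidates: {0.3, 1, 3} h⁻¹;
- `φ` solved from the fasting residual G(0) = G0 + A·sin φ, with the
  π − φ alternative also tried (sine ambiguity).

Bounds: A ≥ 0, α ∈ [0, 20] h⁻¹, T ∈ [0.5, 24] h; (A, φ) is
canonicalized to A ≥ 0, φ ∈ [−π, π).  The winning start is polished
once more; `converged` reflects solver success.  `R²` is 1 − SSR/SST on
the fitted points; the residual SD uses dof = n − 5 (five free
parameters).  A flat series takes a degenerate path (A = 0, G0 = mean,
R² undefined and flagged) rather than an ill-posed optimisation.
Group-level curves are fitted on the pooled (t, glucose) point cloud of
all animals of a group, matching the whole-group convention of the
study design; pooling also tightens parameter error relative to
single-animal fits (verified by simulation in the test suite).

**Identifiability.**  On the standard 0–240 min grid the parameters are
recoverable to < 1e-4 relative error from noiseless data throughout the
physiological region the cohort generator uses (G0 70–200 mg/dL,
A 20–120 mg/dL, α 0.2–2.5 h⁻¹, T 2–8 h, φ within ±1 rad).  Near the
admissible-bound edges the problem degenerates by construction — at
α → 20 h⁻¹ the oscillatory term is numerically extinguished beyond the
first sample, and at T → 24 h the grid covers a sixth of a period — so
recovery claims are stated for the physiological region, not the whole
box.

### Derived parameters

G(0), G(2) and G′(0) are evaluated directly.  Extrema of G and of G′
are located on a dense grid (step 1e-3 h) and refined locally to a
slope tolerance of 1e-6 — rather than via the closed-form root of
tan(ωt + φ) = ω/α — so that horizon truncation is handled uniformly;
the GTT maximum is searched on [0, horizon] (a curve already falling at
t = 0 has its maximum at the fasting draw), while the ITT extremum is
the first local minimum after t = 0.  The model AUC uses the exact
antiderivative; it agrees with adaptive quadrature to 1e-6 relative
over the whole parameter region (property-tested).  Default horizons
are the last sampling times: 4 h (GTT) and 3 h (ITT), configurable.
The ITT panel stops at H′(0), so the steepest-fall fields are reported
as NaN for ITT fits.

## Phenotyping conventions

- Dysglycemia bands are contiguous half-open intervals: prediabetes at
  fasting ∈ [100, 126) or 2-h ∈ [140, 200) mg/dL, diabetes at ≥ 126 /
  ≥ 200; the printed integer bands leave (125, 126) and (199, 200)
  unassigned for non-integer values, and the half-open convention
  closes those gaps.  The overall label is the worse criterion; both
  per-criterion labels are returned.
- HOMA-IR needs insulin in µU/mL; serum insulin is typically assayed in
  ng/mL, and the µU-per-ng factor is assay dependent, so the conversion
  demands an explicit factor and never assumes a default.
- Caloric intake is whole-group kcal per gram of whole-group body mass:
  using energy rather than grams cancels the energy-density difference
  between diets (2.84 vs 3.89 kcal/g), and group mass cancels attrition.
  Period marginal means default to weeks 1–5, 6–10 and 11–18; the
  study's printed windows overlap at week 10 and this package assigns
  week 10 to the early-intervention period (configurable).
- Adipocyte size-class boundaries derive from the linear-interpolation
  quartiles (Q1, median, Q3) of pooled standard-diet areas; the shipped
  defaults are 2,197.5 / 4,395 / 6,592 µm² so binning works without
  reference data.  Bins are half-open upward: an area exactly on a
  boundary joins the larger class.

## Statistics layer

Fixed conventions (the procedures' names alone do not pin variants):
Levene uses the mean as group center; unbalanced factorial ANOVA uses
Type II sums of squares (animals were lost during such studies, so
mild unbalance is the norm); the FDR method is Benjamini–Hochberg; the
split-plot within factor is Greenhouse–Geisser corrected with ε
estimated from the pooled within-group covariance and clamped to
[1/(k−1), 1].  The post-hoc selector is automated: Levene p < 0.05
routes to Games–Howell (Welch-type t, Welch–Satterthwaite df, p from
the studentized range with q = t·√2), otherwise pairwise Welch tests
with Bonferroni adjustment.  Games–Howell and Dunn are implemented
in-package (per-pair z on pooled ranks with tie correction for Dunn)
and are validated against an independent implementation and against
their k = 2 analytic reductions in the test suite.

The split-plot three-way ANOVA (two between factors, one within) is
assembled from an OLS decomposition: between effects are tested against
the subject-within-groups mean square, within effects against the
period × subject residual; subjects with incomplete period measurements
are dropped listwise with a warning.

Type-I error of Levene, Kruskal–Wallis, both two-way ANOVA main effects
and the interaction, and Games–Howell at k = 2 is verified by 2,000
matched null simulations per procedure (within the 99% binomial
interval around 0.05).

## Imaging-MS screen

The analysis unit is a per-sample average peak list (pixel-level
processing is upstream and out of scope; an average over ~500 pixels is
assumed).  TIC normalization divides by the summed intensity;
everything downstream is invariant to per-sample global intensity
scaling.  Alignment pools all peaks, sorts by m/z and chains runs whose
consecutive gaps stay within the ppm tolerance (single linkage,
default 10 ppm to match the annotation tolerance); bin centers are
intensity-weighted means, and a sample contributing two peaks to one
bin keeps the more intense one (logged).  Strong signals are bins whose
summed intensity strictly exceeds 5% of the largest summed intensity.

Statistics treat each technical replicate as a sample by default,
mirroring the emulated design (n = 8 = 4 biological × 2 technical);
`collapse_technical_replicates` averages them instead, since treating
them as independent inflates n.  The screen applies BH-FDR across bins
to the Kruskal–Wallis omnibus p-values and then Dunn tests with
Bonferroni adjustment over the 28 group pairs within significant bins;
the alternative order (FDR across all pooled pairwise p-values) is
available behind a flag.

**A structural note on screen power.**  With 8 groups of 8 samples, the
chi-square(7) reference gives the omnibus KW p-value a floor near 2e-3
even at complete group separation, so a *solitary* non-null bin can
never clear a 74-bin BH step (q ≥ ~0.15) no matter how large its
effect: cross-bin FDR significance in this design requires several
non-null bins lifting each other's BH ranks.  The calibration suite
therefore checks the FDR screen under the global null (flagged fraction
≤ 5%) and checks detection power for a lone 3-fold spiked bin through
the raw KW + Dunn–Bonferroni cascade, where power exceeds 0.9.

PCA is centered (optionally unit-scaled); Ward clustering runs on
per-bin z-scores with Euclidean distance, and leaf order is made
deterministic by optimal leaf ordering.  Annotation computes
theoretical adduct m/z as monoisotopic(M) + cation mass − one electron
mass, with the constants centralized and versioned in
`glucodyn.constants`; hits are reported within ±10 ppm sorted by |ppm|.
The bundled annotation table records two sodium-adduct entries whose
reported m/z values sit ~40 ppm from the computed masses; the table
keeps the discrepancy explicit instead of forcing agreement, as those
annotations are tentative.

## Synthetic cohort

The generator emulates the study design — 4 interventions × 2 sexes ×
8 animals; GTT at weeks 0, 5, 12, 18 on the 0/15/30/45/60/90/120/240
min grid; ITT at week 18 on the 0/…/180 min grid; weekly feeding and
body-mass records; a fasting hormone panel; adipocyte areas; 64 IMS
peak lists.  Group-true curve parameters live in a versioned fixture
(`data/default_dynamics.yaml`) chosen to reproduce the qualitative
ordering of the emulated study (diet-fed liraglutide females highest
setpoint and slowest return, chow males fastest); they are not
quantitative estimates of any real cohort, and per-animal variance of
real data being unreported, the defaults are explicitly arbitrary.

Choices:

- Animal heterogeneity is a lognormal multiplicative effect on A and G0
  only (CV 0.08 by default): curves stay positive and the setpoint
  interpretation survives scaling.
- Measurement noise is Gaussian, SD 5 mg/dL by default (a typical
  glucometer strip error magnitude); simulated values are floored at
  20 mg/dL for physiological plausibility.
- One seed drives everything, substreamed per animal (and per IMS
  sample) via spawn keys, so adding animals never perturbs existing
  draws and cohorts are bit-reproducible.
- Hormone means encode the design's expected contrasts (e.g., elevated
  fasting insulin in liraglutide-treated females); IMS group effects
  multiply designated m/z values (e.g., the 387.01 bin elevated in chow
  males) on top of lognormal baselines with per-sample TIC scaling that
  normalization must cancel.

What passing tests on this cohort do **not** show: the generator has no
estrous-cycle or circadian structure, no drug pharmacokinetics, no
mortality process, no pixel-level spatial correlation in spectra, and
its noise is homoscedastic — real data will violate all of these to
some degree, so end-to-end recovery here validates the machinery, not
field performance.

## Problem sizes in the test suite

Property suites run at the sizes that keep the full run comfortably
interactive: 1,000 parameter draws for the AUC identity, 100 noiseless
recovery draws, 200 replicates for the noisy pooled-fit check, 200
replicates each for the screen null/power calibration, and 2,000 null
simulations per procedure for type-I error.
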