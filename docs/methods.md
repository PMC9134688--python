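# Methods

This note documents the models implemented in `myelinquant`, the defaults
chosen where the design was open, and what the synthetic-data generator
does and does not emulate.

## Diffusion tensor estimation

Each voxel's diffusion-weighted signal is modelled as
`S_i = S0 · exp(−b_i · gᵢᵀ D gᵢ)` with a symmetric tensor `D` (mm²/s).
Taking logs gives a linear model in `(Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, ln S0)`
that is solved by ordinary least squares — plain OLS, no variance
weighting or positivity constraints. Scalar maps follow from the sorted
eigenvalues λ₁ ≥ λ₂ ≥ λ₃: AD = λ₁, RD = (λ₂+λ₃)/2, MD = mean, and

    FA = √(3/2) · ‖λ − λ̄‖ / ‖λ‖.

Numerical choices:

- **Signal positivity.** Log-linear fitting requires S > 0. Non-positive
  signals (possible after noise at high b-value) are replaced by the
  voxel's smallest positive signal × 10⁻³. Voxels containing non-finite
  signals are excluded from the output mask instead of raising.
- **Negative eigenvalues** (noise can push λ₃ < 0) are clamped to 0 for FA
  only, keeping FA ∈ [0, 1]; raw eigenvalues feed AD/RD/MD so diffusivity
  estimates stay unbiased. An all-zero eigenvalue triple defines FA = 0.
- **Identifiability.** The design matrix must have column rank 7; schemes
  with fewer than 6 distinct non-collinear weighted directions are
  rejected up front.

## Forebrain FA-histogram analysis

FA values from one large forebrain ROI are binned into 100 half-open bins
of width 0.01 on [0, 1] (the final bin closed at 1.0) and normalized to
sum 1. No low-FA thresholding is applied: the point of the global
histogram analysis is to avoid the arbitrary FA cutoffs of manual ROI
work, so empty and low bins stay in.

Each subject's histogram is summarized by the Burr type XII distribution
`F(x; c, k, α) = 1 − (1 + (x/α)^c)^(−k)` (all three parameters positive),
whose closed forms give the descriptors:

- median = α(2^{1/k} − 1)^{1/c}
- mode = α((c−1)/(kc+1))^{1/c} for c > 1, else 0 (the density peaks at 0)
- mean = αk·B(k − 1/c, 1 + 1/c), reported as undefined when c·k ≤ 1.

**Fit objective.** Least squares between observed bin heights and model
bin probabilities computed as CDF differences across the bin edges,
renormalized by the Burr mass on [0, 1]. CDF differences (rather than
pdf × width) are exact for coarse bins; the renormalization makes the
model a proper distribution on the same support as FA, so a histogram
built from exact Burr bin probabilities is recovered to optimizer
precision (~10⁻⁷ relative in practice). Maximum likelihood would also be
defensible; least squares on the binned representation matches what the
analysis actually compares between groups (histogram shapes).

**Optimization.** α is initialized from the empirical (interpolated)
histogram median; (c, k) are scanned over the grid {1, 2, 4, 8} ×
{0.5, 1, 2, 4} with α adjusted so every start matches the empirical
median. The four best starts by raw objective are refined with bounded
trust-region least squares (tolerances 10⁻¹⁴, bounds c, k ∈ [10⁻³, 200],
α ∈ [10⁻⁶, 10]); the best refined solution wins and carries a convergence
flag. A histogram with all mass in one bin is rejected as degenerate.

The group shift is tested with Welch's *t*-test on the chosen descriptor
(median by default, matching the primary readout); group-average
histograms are the arithmetic mean of subject heights, renormalized.

## Regional statistics

Regional means pool all voxels carrying a label (bilateral structures
share one label, so hemispheres pool before averaging). Group comparisons
per region × metric use Student's *t*; multiplicity across the ten
regions is handled by the Benjamini–Krieger–Yekutieli two-stage adaptive
step-up at q = 0.1: stage 1 is Benjamini–Hochberg at q′ = q/(1+q), the
stage-1 rejection count r₁ estimates the null fraction, and stage 2
re-runs BH at q′·m/(m−r₁) (rejecting none if r₁ = 0, all if r₁ = m).
Reported q-values are the smallest nominal level at which the full
two-stage rule rejects, found by bisection; because the procedure is
adaptive they can legitimately fall below the raw p-value. Fisher's exact
test uses the two-sided probability-mass rule (summing all tables with
the observed margins whose probability does not exceed the observed
one). Two-way ANOVA uses type-II sums of squares with Tukey's
studentized-range post-hoc test over all treatment × age cells;
treatment contrasts within each age are flagged, since those are the
comparisons of scientific interest. Both the Tukey route and the
*t*-test + FDR route are available for area-fraction data; neither is
privileged.

## ELISA quantification

The standard curve is a four-parameter logistic on blank-subtracted
signals, `y = lower + (upper − lower)/(1 + (x/ec50)^(−slope))`, fitted by
least squares. Back-calculation inverts the 4PL over its open response
range; signals at or above the upper asymptote are flagged saturated and
below-range signals flagged rather than extrapolated. The LLOQ is defined
as the lowest standard whose back-calculated concentration recovers its
nominal within the assay's own 70–120 % acceptance band — the same band
applied to spike-and-recovery percentages
`(spiked − base)/nominal × 100` and to dilution-linearity percentages
(each step relative to the least-diluted estimate). The choice of 4PL is
the immunoassay default for sigmoidal standard curves; no detection-
chemistry modelling is attempted (plates reduce to signal tables).

## IHC area fraction

A pixel is MBP-positive when |pixel − background| exceeds a threshold,
counted within the hemisphere mask and expressed as a percentage of the
mask area. The threshold is a configuration parameter because instrument
thresholds do not transfer across rigs; the default is Otsu's split of
the masked |pixel − background| distribution, which separates the
background and stain intensity modes without manual input. Percent area
is non-increasing in the threshold by construction.

## Synthetic-data generator

The generator produces every pipeline input with known ground truth. Its
defaults are the study conditions; they were fixed once and are not
tuning knobs.

- **Gradient scheme**: 30 directions at b = 970 s/mm² plus one b = 0,
  constructed as a golden-angle (Fibonacci) spiral on the upper
  hemisphere — diffusion weighting senses only axes, and the hemisphere
  spiral stays well-conditioned down to the 6-direction identifiability
  limit, where a full-sphere spiral is degenerate. A seeded rotation
  decorrelates direction sets across seeds.
- **Phantom**: 16 × 16 × 10 voxels, ten rectangular tracts (one per
  white-matter label, ~28 % of the volume) of prolate tensors with axial
  diffusivity 1.2 × 10⁻³ mm²/s and radial diffusivity 5 × 10⁻⁴ mm²/s in
  vehicle animals, reduced 25 % in treated animals; isotropic
  compartment 7 × 10⁻⁴ mm²/s. Background voxels are partial-volume
  mixtures: a randomly oriented anisotropic compartment blended with the
  isotropic one at a per-voxel weight uniform on [0, 1], fixed across
  subjects. This mixing is what gives the forebrain histogram its
  brain-like shape — a low-FA peak with a heavy right tail — and makes
  the treatment effect a whole-distribution shift rather than a moving
  spike; a purely isotropic background produces a bimodal histogram
  whose Burr median tracks the noise peak instead of the biology.
- **Noise**: Rician on magnitude signals, σ = S0/SNR with SNR = 25 and
  S0 = 1000, typical of preclinical DWI magnitudes. SNR = ∞ returns the
  exact forward model (used by the round-trip tests).
- **MBP development**: logistic in age with plateau 100 ng/mL, vehicle
  midpoint PND 8.5, scale 1.5 d; treatment shifts the midpoint 2 d
  earlier, so group separation is largest late in the dosing window and
  MBP is still rising at PND 11, matching the developmental profile the
  two-way ANOVA and the same-pup correlation rely on. Noise is
  multiplicative Gaussian (CV 0.15), floored at 0.
- **Plates**: 2-fold standard series from 100 ng/mL (7 points + blank)
  through a 4PL with multiplicative noise; samples are measured at their
  diluted concentration.
- **IHC images**: exactly ⌈fraction × mask area⌋ randomly placed
  foreground pixels inside an elliptical hemisphere mask, plus Gaussian
  noise, returning the realized exact fraction.
- **Teeth**: independent Bernoulli eruption per pup with group-specific
  probabilities (defaults 0.8 vs 0.1, n = 11/group).

Every `simulate_*` function is bit-reproducible given its seed, and the
full pipeline derives all stage seeds from one root seed, so a study run
is byte-identical under a fixed seed and configuration.

**What the generator does not emulate**: k-space/EPI artifacts, eddy
currents, motion, spatially structured anatomy (tracts are axis-aligned
slabs), subject-to-subject anatomical variability (subjects differ only
through noise), detection-chemistry physics, and stain morphology
(positive pixels are scattered, not contiguous). Consequently, passing
tests demonstrate the correctness and statistical behavior of the
estimators under the stated forward models — not robustness to
real-world acquisition artifacts or biological heterogeneity.

## Problem sizes

The default study runs 12 subjects on the 16 × 16 × 10 grid with 31
volumes each; power and correlation properties are assessed over 20
replicate studies, FDR control over 5,000 replicates of 10 tests, and
distribution round trips at 5 × 10⁴ samples. These sizes give stable
Monte-Carlo estimates while keeping a full verification run in the
minutes range on a single core.

## Known limitations

- OLS tensor fitting is unweighted; at very low SNR the log transform
  biases diffusivities (the standard caveat for log-linear fits).
- The Burr family is assumed adequate for forebrain FA histograms; no
  alternative families (beta, gamma) or goodness-of-fit selection are
  provided.
- The BKY q-value is defined procedurally (smallest rejecting level) and
  computed by bisection; it is not an estimate of positive FDR.
- ELISA replicate-level CV acceptance is applied only when replicates
  exist; single-well plates rely on the recovery band alone.
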