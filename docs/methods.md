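# Methods

## The measurement model

A DiBAC4(3) assay scores a cell as depolarized when its mean fluorescence
exceeds a threshold anchored to a control population. The package models the
whole chain from field of view to population statistics.

**Cell geometry and placement.** Cells are 2-D capsules (rectangles with
semicircular caps), the natural planform of rod-shaped bacilli; lengths are
drawn uniformly from 18–30 px and widths from 4–7 px, matching ~4 µm × 0.8 µm
rods at a 40× objective (~0.16 µm/px). Scenes are built by rejection
sampling with a hard non-overlap constraint (minimum capsule-to-capsule
distance of the sum of radii plus a 1 px gap) and a bounded number of
attempts per object; failure raises a "scene too dense" error rather than
silently producing overlapping objects. Touching cells are therefore absent
from clean benchmarks by construction; when overlap is forced (as in the
merged-pair tests), the segmenter deliberately does **not** split the merged
component — there is no principled splitting rule without a shape prior, so
merging is treated as a quantified failure mode rather than hidden by a
watershed heuristic.

**Intensities.** Per-cell true intensities follow a two-component log-normal
mixture: polarized cells at log-location ln 10 and depolarized cells at
ln 18, both with log-scale 0.35 (arbitrary units). A skewed, strictly
positive family is the right shape for fluorescence intensity data, and
these defaults put a mixed control population's pooled mean near the
~10–30 a.u. working range of typical DiBAC micrograph analyses. Because the
two classes overlap, the fraction of cells above the control-mean threshold
is *not* the latent class fraction; all recovery tests compare against the
analytic mixture tail
P(I > q) = f·S_d(q) + (1−f)·S_p(q) (log-normal survival functions), never
against the latent fraction itself.

**Imaging.** Brightfield: uniform background (default 3000 a.u.) with cell
interiors darkened to 35% of background. Fluorescence: uniform per-cell
emission added to a background of 2 a.u., optionally convolved with a
Gaussian PSF (default σ = 0.8 px), plus additive Gaussian read noise on both
channels; values are rounded and clipped to the 16-bit range (with a warning
on overflow). This is a statistical stand-in, not an optics model: no
shading, no depth effects, no shot-noise scaling with signal. Acquisition
noise statistics of real instruments vary widely, so the noise parameters
are free configuration and no claim is made that they match any particular
microscope.

**Replicate clustering.** Biological replicates share culture history, so
their cells are positively correlated. The generator injects this on the
logit scale: within replicate *j*, cells are depolarized with probability
expit(logit(f) + b_j), b_j ~ N(0, replicate_sd²), the same structure a
population-averaged logistic model with a panel variable assumes. The
default replicate_sd of 0.1 produces between-replicate SEMs of a few
percentage points at n ≈ 1000 cells/replicate, the order seen in triplicate
bench experiments. The dose–response generator gives each replicate one
random intercept shared across all doses, because a biological replicate
spans the whole KCl series.

## Segmentation

Cells are identified on the inverted brightfield image by a global
threshold — Otsu by default, isodata and mean available — followed by
connected-component labelling (8-connectivity by default; rods at arbitrary
angles fragment under 4-connectivity). The size filter keeps regions with
area in [min, max]; when not set explicitly these default to 0.25× and 4×
the median single-cell capsule area of the generating geometry. No
background subtraction is applied before averaging intensities: debris and
specks are removed by the size filter, and a constant background offset
cancels in any threshold comparison because the threshold is measured on the
same scale.

## Depolarization read-outs

* Threshold = arithmetic mean intensity of control cells **pooled across
  replicates** (not a mean of replicate means; with unequal replicate sizes
  the two differ).
* "Above the threshold" is strict (>): a cell exactly at the control mean
  counts as polarized. The choice is a tie-break convention; with continuous
  intensities it is almost surely irrelevant.
* Percentages are computed per biological replicate; the condition summary
  is their mean ± SEM (SD/√N across replicates, NaN for a single
  replicate).
* Histograms pool replicates of a condition, use fixed-width bins from 0
  (default width 1 a.u.), and are normalized by the modal bin count so the
  most frequent intensity has height 1.

## The GEE estimator

The marginal model is logit P(y=1|x) = x'β with Var(y) = µ(1−µ) (binomial)
and working correlation R(α) within clusters, either independence or
exchangeable. Estimation is Fisher scoring on the estimating equations
Σᵢ Dᵢ'Vᵢ⁻¹(yᵢ−µᵢ) = 0 with Vᵢ = φ Aᵢ^{1/2} R Aᵢ^{1/2}; the exchangeable α
is re-estimated each iteration by the moment estimator (sum of
cross-products of Pearson residuals over within-cluster pairs, scaled by φ
with the usual p-degree-of-freedom correction), and R⁻¹ is applied in
closed form via Sherman–Morrison, so each iteration costs O(Np). The
convergence criterion is a relative step tolerance of 1e−8 with a cap of
100 iterations. Reported covariance is the Liang–Zeger sandwich
B⁻¹MB⁻¹ clustered on the replicate; with a single cluster the sandwich is
undefined and the model-based covariance φB⁻¹ is returned with a warning.
Inference is Wald (z = β/SE, normal reference), the standard GEE report.
Degenerate cases: fitted probabilities reaching exactly 0/1, a singular
information matrix, or a diverging linear predictor raise a
complete-separation error naming the offending covariate.

Grouped binomial data (x, n_total, n_depolarized) are fitted by the same
scoring loop with the counts as prior weights and independence working
correlation; point estimates are identical to expanding the groups into 0/1
rows. This is what lets a published table of per-condition percentages and
sample sizes reproduce a dose–response coefficient: counts are reconstructed
by half-up rounding of percentage × n (the convention of printed tables),
and a ±1 perturbation of any reconstructed count moves the fitted KCl slope
by < 5·10⁻⁶, far below printed precision.

Relative risk is reported as the ratio of marginal probabilities
(comparison over reference). In the pairwise comparison routine both
probabilities come from the fitted two-group GEE, and the p-value is the
Wald test of the group indicator; p-values are unadjusted by default (a
Bonferroni option exists) since all-pairs panels in this field are
conventionally reported unadjusted.

Working correlation defaults to exchangeable — the natural reading of
replicate-as-panel clustering. Independence mode exists both as a fitting
option and because aggregate tables without replicate structure can only be
fitted that way.

## Physiology

Nernst potentials use R = 8.314462618 J mol⁻¹ K⁻¹, F = 96485.332 C mol⁻¹,
default T = 310.15 K (37 °C incubation), z = +1, [K⁺]in = 300 mM and a
3 mM extracellular baseline (1× PBS). With these constants the
15/60/300 mM added-KCl steps evaluate to −75.19, −41.71 and +0.27 mV
(−75/−40/0 after the 5 mV presentation rounding); the 0 mM resting condition
evaluates to −123.1 mV. Computation is never rounded — rounding is applied
only on explicit request for reporting.

The specific growth rate r_t is the slope of a least-squares line through
ln(OD) over a window of samples centred on t (default 3 points), i.e. a
local estimate of d ln N/dt in min⁻¹. On the logistic generator this
reproduces the closed form r_max(1 − N/K) and decreases monotonically
through the growth curve, the qualitative signature of a culture leaving
exponential phase. A doubling time of ~64 min corresponds to
r ≈ 0.0108 min⁻¹.

## Pipeline reproducibility

All randomness flows through explicit integer seeds; there is no global
random state. The pipeline derives per-stage seeds by SHA-256 hashing of
(master seed, stage, condition, replicate, image), truncated below 2³¹, so
any stage can be re-run in isolation. Identical config + master seed yields
byte-identical summary tables; the manifest records the config hash, all
derived seeds and every artifact path.

## Problem sizes used in the validation suite

The test suite runs at desk scale: scenes of 50 cells (plus 35 debris
objects) in 512×512 frames, 20 scenes per recovery check, fast-path tables
of 10⁴–10⁵ cells for distributional identities, and 200 simulated
experiments at the KCl design (4 doses × 3 replicates × 1000 cells) for
slope-recovery calibration. These sizes give Monte-Carlo error bars
comfortably inside the 3-SD acceptance bands while keeping the full suite
under a minute.

## Limitations

* The generator's debris model (non-fluorescent specks and dim circular
  blobs) exercises the size filter, not the full menagerie of real
  non-cellular material.
* No PSF-induced intensity bias correction: with nonzero blur, measured
  per-cell means are slightly below true emission; recovery tests therefore
  use blur-free rendering, and real-data use should treat absolute
  intensities as relative quantities (as threshold-based scoring does).
* Segmentation assumes well-separated cells; dense fields or chains are
  undercounted by design (no splitting).
* Percent-depolarized values from real published experiments depend on
  unobservable instrument and macro details; they are used here only as
  realistic preset fractions for the generator, and simulated imagery makes
  no claim to reproduce any specific study's micrograph-level numbers.
* The GEE implementation covers one grouping level (biological replicate).
  Technical replicates within biological replicates are not modelled as a
  second level; they are treated as part of the cluster.
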