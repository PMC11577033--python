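# Methods

## Signal model and fitting

Each voxel of a multi-echo gradient-echo magnitude acquisition is modelled
as S(TE) = S0·exp(−TE/T2*), with TE in ms. The default estimator is
nonlinear least squares over all echoes, initialized by the closed-form
ordinary least-squares regression of log S on TE and refined with an
analytic Jacobian (bounds S0 ≥ 0, T2* > 0; tolerances 1e-12). The
initialization is deterministic and there is no randomness anywhere in the
fit, so identical inputs always give identical maps. A pure log-linear
estimator (`method="loglin"`) is kept for comparison; it is faster but
down-weights late echoes incorrectly under noise.

Degenerate voxels never raise: any non-positive echo magnitude marks the
voxel invalid (the model is fit over *all* echoes or not at all, so a
zero echo leaves no defensible partial fit), and a non-decaying signal
(log-linear rate ≤ 0) is reported at the T2* cap with a `non_decaying`
flag and `valid=False`. The cap defaults to 1000 ms — generous for any
placental tissue at these field strengths but bounding runaway estimates
in fluid or noise-only voxels — and is configurable. Fit quality is the
R² of the exponential model in signal space. No Rician noise-floor or
offset term is fitted by default: the model is the plain mono-exponential.

Protocol constants: echo trains 46/120/194/268 ms (0.55T),
7.84/60.574/113.308/116.041 ms (1.5T), 13.8/70.4/127.0/183.6 ms (3T);
nominal isotropic voxel sizes 3.1, 2.5 and 3.0 mm respectively.

## Metric suite

All metrics are orientation-invariant, so volumes are used in their
on-disk axis order and never resampled; masks must share the grid of the
volume they describe (nearest-neighbour interpretation only, no
registration).

- **Histogram statistics** (mean, skewness, excess/Fisher kurtosis) use
  the valid fitted T2* values inside the mask, population (divide-by-n)
  moments. At least 8 valid voxels are required. A numerically constant
  sample has undefined shape moments; both are reported as 0 with a
  `degenerate_histogram` flag.
- **Volume** is exactly voxel count × voxel volume (ml).
- The **morphological map** is the Euclidean distance transform of the
  mask with anisotropy-aware sampling weights, center-to-center
  convention: an isolated voxel is one voxel spacing from background. The
  grid border counts as non-placental (unmeasured space cannot be
  placenta), which keeps distances bounded for masks touching the edge.
- **Non-uniformity** is mean + SD of the morphological-map values.
  Population SD by default; `ddof=1` switches conventions, changing the
  spread term by √(n/(n−1)).
- **Maximal thickness** is twice the map's maximum.
- Voxels whose fit failed are excluded from histogram statistics but kept
  for volume and morphology: those are properties of the segmentation,
  not of the fit.

## Normative curves and z-scores

μ(GA) is polynomial in gestational age, default degree 2: the published
per-decade drops are unequal at every field, which excludes a straight
line, and a quadratic is the minimal family that interpolates three
anchors. Fitting a cohort uses least squares; σ is either the residual SD
(ddof = number of mean parameters) or, in `linear` mode, a regression of
|residual| on GA rescaled by √(π/2) (the Gaussian mean-absolute-deviation
factor).

The built-in reference per field is the exact quadratic through the three
published anchor means at 20/30/40 weeks. Its σ(GA) interpolates the
published bracket half-widths divided by 1.96, i.e. the brackets are read
as 95% intervals of the predicted mean. This interpretation is a
documented choice (the alternative — prediction intervals — would widen σ
considerably); it makes built-in z-scores sensitive, whereas curves refit
to a cohort use the residual SD and give z-scores on the familiar
standard-normal scale. z-scores are always computed within a single
field's curve; cross-field comparability is an emergent property of the
construction, not a shared model. Evaluation outside the curve's GA
support [20, 40] (or the fitted cohort's range) is computed but flagged
`within_range=False`, never silently returned.

## Synthetic phantom and cohorts

The phantom emulates a coronal multi-echo stack of the gravid uterus at
desk scale: a placental compartment (slab, default 20 mm constructed
thickness on a 40×40×24 grid, or a half-ellipsoid cap), a 2-voxel
uterine-wall rind, and amniotic fluid elsewhere. Placental T2* is the
built-in normative mean for the requested field and GA plus a
heterogeneity field — Gaussian-blurred white noise with a correlation
length in mm (default 12) and an amplitude that defaults to 10% of the
mean scaled by GA/30, mimicking the increase of parenchymal heterogeneity
with gestation. Compartment defaults (fluid 300 ms scaled by the field's
normative level relative to 3T; wall at half the placental mean; S0
1400/800/1000) are illustrative contrast choices, not literature-calibrated
tissue values.

Noise is Gaussian or Rician (magnitude of complex signal with independent
Gaussian noise on both channels); SNR is defined at the first echo within
the placental compartment, which makes the noise level unambiguous and
testable. One seed drives everything through a `SeedSequence` split into
independent child streams (heterogeneity, noise), so phantoms are
bit-reproducible.

Cohort simulation draws GA uniformly on an interval (default 17–40 weeks,
matching the built-in curves' neighbourhood) and mean T2* from the
built-in curve plus Gaussian residual noise (default SD 15 ms, which
reproduces the strong negative Spearman trend of mean T2* against GA seen
in healthy cohorts of n≈100). Non-positive draws — possible only at
implausibly large SD — are rejected and redrawn deterministically.

What the phantom does *not* emulate: real anatomy, EPI geometric
distortion, motion, B0/B1 inhomogeneity, partial-volume mixing at the
placental boundary, and segmentation error (the mask is the generating
compartment itself). Passing tests therefore demonstrate correctness of
the fitting, metric and normative machinery under the stated noise model,
not robustness to acquisition artefacts on clinical data.

## Problem sizes and numerical choices

Default test problem sizes: phantom grids of 16³–40×40×24 voxels
(≈600–7000 placental voxels), cohorts of n = 98–200, 100-repetition trend
checks, and 50 random 16³ masks for distance-transform verification
against an exhaustive nearest-background search. The grid-search oracle
for the voxel fit spans S0 ∈ [0, 2000] step 1 and T2* ∈ [1, 400] ms step
0.1. Ties in the distance transform are irrelevant to the reported
metrics (only values, not argmins, are used). CSV/JSON outputs are
written with sorted keys and fixed column order, so identical inputs give
byte-identical result files.

## Known limitations

- The segmentation itself is out of scope: the pipeline takes a binary
  mask as input (any external segmenter can be plugged in upstream).
- The mono-exponential model ignores the Rician noise floor; at very low
  SNR late echoes bias T2* upward. The high-SNR consistency checks run at
  SNR 50 where this bias is ≪ 2%.
- Built-in σ is tight (see above); z-scores from the built-in reference
  and from refit cohort curves are on different spread scales and should
  not be mixed within one analysis.
- Normative curves are valid only on their GA support; extrapolation is
  flagged, not forbidden.
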