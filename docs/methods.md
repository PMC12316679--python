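# Methods

This note documents the models, estimators, numerical choices and known
limitations of `vaimri`.

## Signal model and relaxometry

Dynamic GE/SE signals are converted to relaxation-rate changes
ΔR(t) = −ln(S(t)/S₀)/TE, with S₀ the arithmetic mean of the pre-contrast
dynamics (default dynamics 0–7; the contrast agent is injected at the
start of the 9th dynamic).  The baseline range is configurable because
some protocols discard initial non-steady-state dynamics.  Non-positive
signals make the log undefined; such voxel-timepoints propagate as missing
values and any analysis window containing one excludes the voxel from the
Q/VSI/MTI maps — imputation would bias the loop areas.

The bolus peak is detected on the GE curve (the larger susceptibility
effect), by default on the mean ΔR2\* curve over the analysis mask, and
the same window indices — 4 dynamics before to 8 after the peak, clamped
at the acquisition bounds with a flag — are applied to both curves.  No
smoothing is applied by default; an optional width-3 moving average exists
for noisy phantoms.

## Q estimator

Q = ΔR2/(ΔR2\*)^(2/3) must be reduced to one number per voxel from 13
paired window samples.  Three estimators are implemented
(`q_estimator` switch):

- `slope` (default): through-origin least-squares slope of ΔR2 on
  (ΔR2\*)^(2/3).  It is exact whenever the two curves obey the power law
  with a common constant, and weights low-amplitude window edges weakly,
  which makes it robust to noise.
- `ratio_of_means`: mean(ΔR2)/mean(ΔR2\*)^(2/3).  By Jensen's inequality
  this is biased low when ΔR2\* varies strongly over the window (about
  −7% for a typical first-pass shape at Δt = 1.6 s; within 5% when the
  window variation stays below a factor of two).
- `pointwise`: mean of pointwise ratios; exact noise-free but unstable at
  low-amplitude window edges.

The slope estimator is the default precisely because of the
ratio-of-means window bias; the choice matters at the few-percent level
for realistic bolus shapes.

## VSI and units

VSI = 0.867·√(D·rCBV)·Q^(−3/2).  The unit contract is D in µm²/s and Q in
s^(−1/3), giving VSI in µm (√(µm²/s)·s^(1/2) = µm); the diffusion module
exposes D in both mm²/s (native) and µm²/s (×10⁶).  Voxels with any
non-positive input are flagged invalid rather than clipped.  Voxels with
VSI > 50 µm are retained in maps but counted separately in the histogram
output, since they are rare and dominated by residual large-vessel signal.

## MTI sign convention

The vortex curve plots ΔR2\*(t) (ordinate) against ΔR2(t) (abscissa) over
the window, closed last-to-first, and MTI is the negated shoelace sum so
that a **clockwise** loop is **positive**.  Physically, when the bolus
reaches arterioles before capillaries the GE effect leads the SE effect
and the loop runs clockwise (positive MTI, arteriole dominance); the
reverse ordering gives venule dominance and negative MTI.  MTI is the raw
loop area in s⁻² — not normalised by bolus amplitude — and ROI values are
means of voxel-wise areas.  Two numerical facts matter:

- a perfectly lag-free voxel does not give exactly zero: the polygon
  samples a curved (but loop-free) trajectory at different points on the
  way up and down, leaving a discretisation residue of a few percent of a
  1.6 s-lag loop area (it vanishes for straight-line trajectories and as
  Δt → 0);
- MTI is exactly antisymmetric under time reversal and invariant under
  cyclic rotation of the window vertices.

## Perfusion

The AIF is the mean ΔR2\* curve of the best arterial voxels, ranked
deterministically by early arrival (10%-of-peak crossing), high peak and
narrow FWHM (sum of ranks, default top 10) — a reproducible stand-in for
manual arterial voxel selection; an explicit voxel list can be supplied
instead.

Gamma-variate curves y(t) = k·(t−t₀)^α·exp(−(t−t₀)/β) are fitted by
bounded least squares with moment-based initialisation (t₀ from the
10%-of-peak crossing; α, β from the first two moments of the curve above
arrival; k from the peak value, computed in log space).  Fits use the full
curve with t₀ free; a window-restricted mode exists.  rCBV is the ratio of
the closed-form integrals k·β^(α+1)·Γ(α+1) of the tissue fit and the AIF
fit — the analytic form isolates the first pass from recirculation, which
is why no numeric trapezoid is used by default.  Identical curves share
one fit (deduplication), which makes piecewise-constant phantoms cheap.

The AIF amplitude is then rescaled so the mean rCBV over normal-appearing
white matter equals 3.2%, a literature anchor for elderly white matter;
the anchoring absorbs any global amplitude uncertainty in the AIF, and a
sensitivity mode disables it.  Afterwards the 10% highest-rCBV voxels over
the union of analysis ROIs are excluded (90th percentile, linear
interpolation, strictly-above rule — all-equal inputs therefore exclude
nothing); a per-ROI scope is available by flag.

CBF is estimated by block-circulant SVD deconvolution: AIF and tissue
curves are zero-padded to twice their length, the circulant AIF matrix
(rectangle-rule discretisation, Δt·C) is decomposed once, and the
singular-value cutoff is raised along a geometric grid from 10⁻⁶ to 0.5 of
the largest singular value until the oscillation index of the
reconstructed flow-scaled residue falls below the threshold (default
0.095, configurable); if the search exhausts, the smallest-oscillation
solution is returned with a warning.  The non-zero lower end of the grid
is a numerical floor guarding the near-null space of the smooth AIF
kernel — without it, fine time grids amplify the circulant model's
wrap-around inconsistency into large spurious peaks.  CBF = max of the
deconvolved function, in relative units; absolute calibration is out of
scope.  GE curves give perfusion through all vessels, SE curves through
microvessels only, so SE-derived CBF ≤ GE-derived CBF whenever the SE
compartment is a subset of the GE compartment.

## Diffusion

The direction-averaged signal is the geometric mean over the three
orthogonal directions, so the fitted D equals the mean of per-direction
ADCs (log of geometric mean = mean of logs); an arithmetic-mean mode
exists.  D is minus the OLS slope of ln(S) on b for b ≥ 200 s/mm²
(unweighted by default, signal²-weighted mode for noisy data).  Excluding
b = 0 removes intravascular (perfusion) contamination.  Voxels with a
non-positive fitted signal are invalid; non-positive D is kept but
flagged implausible (with a 10⁻¹² mm²/s floor so rounding residue on flat
decays still registers).

## ROI rules

NAWM excludes WMH voxels, a 1 cm periventricular zone (3D Euclidean
distance transform, anisotropy-aware, center-to-center, boundary
*inclusive*: exactly 10 mm is excluded) and the manual lesion mask;
all analysis ROIs subtract the lesion mask.  Construction is idempotent.
Distances are center-to-center on the voxel grid with no sub-voxel surface
modelling, which is honest at the 3×3.3×5 mm acquisition resolution.
Summaries report mean, SD (n−1), median and IQR = Q3−Q1 with the
linear-interpolation quantile rule (fixed and documented because the IQR
comparison is a headline analysis); the default is the mean of voxel-wise
values over the valid ROI mask, with a curve-averaging alternative behind
a switch.

## Statistics

OLS with t-based two-sided p-values and 95% CIs (n−k df).  The independent
t-test pools variances by default (Welch by flag); age is mean-centered
before forming the group×age product (raw mode by flag).  No
multiple-testing correction is applied — a deliberate mirror of the
source design and a documented limitation.  Zero-variance inputs raise
rather than returning p = 0.

## Phantom generator

The generator is the forward model run in reverse order of the pipeline:
gamma-variate arterial bolus (default k = 1, t₀ = 14.4 s, α = 3,
β = 1.5 s on a 100×1.6 s grid, injection at the 9th dynamic);
tissue concentration = AIF ⊛ exp(−t/MTT) scaled so the numeric integral
ratio to the AIF equals the tissue's rCBV; ΔR2\* linear in concentration
(scale chosen so the NAWM peak is ~10 s⁻¹, a physiologic value at
TE = 25/78 ms); ΔR2 = q·[ΔR2\*(t−τ)]^(2/3) with a pure time shift τ whose
sign encodes vessel-type dominance; signals S = S₀·exp(−ΔR·TE); DWI
mono-exponential and direction-independent; optional seeded Rician noise
on magnitudes (SNR defined on the pre-contrast baseline).  The model runs
on a 16× oversampled time grid before sampling at the acquisition times.

Default tissue parameters (Q in s^(−1/3), rCBV fraction, D in mm²/s, MTT
in s, τ in s): CGM 0.45/0.055/8.5e−4/3.5/−0.8; DGM 0.44/0.045/7.5e−4/3.5/
−0.8; NAWM 0.39/0.032/8e−4/4.0/−0.8; WMH 0.29/0.028/1e−3/5.0/−0.8;
arteries are pure blood (rCBV 1, MTT 1 s); ventricles carry no bolus.
These place NAWM at the reported elderly-cohort scale (Q 0.39, rCBV 3.2%,
VSI ≈ 18 µm), lesions at lower density / higher VSI, and a negative τ
everywhere, matching the venule-dominated (negative MTI) pattern of brain
tissue.  The SE compartment is the same first-pass shape as GE with a pure
shift — the minimal construction under which Q, VSI and MTI are all
identifiable; explicit arteriole/capillary/venule mixtures, leakage,
motion and distortion are *not* modelled.  Passing tests on the phantom
therefore demonstrates correctness of the inverse computations, not
robustness to real-data artifacts.

The cohort simulator draws subject-level ROI means from linear models
(baseline + group effect + age slope + sex effect + Gaussian noise) with
default effect directions matching small vessel disease (lower Q, higher
VSI, higher MTI in patients) and a 40/21 patient/control default split.

## Problem sizes and numerical choices

Default phantom grid 32×32×8 at 3×3.3×5 mm; 100 dynamics.  The noise-free
default phantom recovers per-tissue Q within 2%, D within 0.1%,
pre-anchor rCBV within 3% and VSI within 5% of its closed form; the oSVD
oracle (finely sampled forward simulation at Δt = 0.1 s, MTT = 4 s)
recovers CBF within 10% — dominated by the truncation bias intrinsic to
regularised SVD deconvolution of smooth kernels.  Statistical calibration
uses 2000 seeded null cohorts of n = 60.  Maps are written as float32
NIfTI; voxel indices are 0-based; affines are carried through untouched
and nothing is resampled.

## Known limitations

- MTI normalisation: raw loop area in the acquisition's rate units; if a
  study normalises by bolus amplitude, values scale accordingly.
- CBF is relative; no absolute calibration and no leakage correction
  (handled by a contrast preload at acquisition in the source protocol).
- The AIF ranking replaces a semi-automatic manual step; on pathological
  arterial anatomy a manual voxel list should be supplied.
- Tissue gamma-variate fits assume a single first pass; strong
  recirculation would require the window-restricted fitting mode.
- All inputs are assumed co-registered on one grid; registration, motion
  and distortion correction are upstream.
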