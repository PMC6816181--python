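# Methods

This note documents the models, numerical choices and known limitations of
the `stormbird` pipeline, in the order the stages run.

## Ingestion and track quality control

Canonical units are kPa (pressure) and km/h (wind and flight speed);
converters (hPa ×0.1, inHg ×3.3864, m/s ×3.6, knots ×1.852) live only at
the I/O boundary, and all timestamps are UTC with no local-time logic.
Malformed rows — unparseable timestamps, out-of-bounds coordinates,
duplicate (individual, time) keys — are counted and reported with line
numbers, then skipped; nothing is imputed.

The speed filter is a sequential greedy pass: the first fix is kept, and
each subsequent fix is removed when its arrival speed from the previous
*kept* fix is ≥ 65 km/h (the threshold is inclusive). This replaces the
irreproducible manual step of visually flagging implausible relocations
with a deterministic rule plus a removal log for human review; the pass is
idempotent and guarantees the output contains no above-threshold pair.

Bursts are maximal runs of fixes with inter-fix gaps ≤ 6 h. The default of
6 h is 4× the 90-min fix interval, so the transmitters' 36-h off cycle
always starts a new burst and no kinematic step ever spans a dormant
period.

## Step geometry

Distances are haversine great-circle values on a sphere of radius
6371.0 km; at the < 300 km displacements relevant here the spherical
approximation differs from an ellipsoidal geodesic by well under 0.5 %, so
no projection library is used. The turning angle is the absolute change in
initial bearing between successive steps, wrapped to [0, π] (a signed
variant in (−π, π] is available behind a flag). Zero-length steps carry the
last moving bearing forward so that a subsequent move yields a meaningful
turn; if no moving step precedes them the turn is flagged undefined. The
first step of every burst has an undefined turning angle; such fixes are
excluded from mixture fitting and labeled by the velocity delimiter alone.

## Utilization distribution and core range

The monthly utilization distribution pools all individuals' fixes — the
analysis needs one shared "core spatial area" per event, and a pooled
cohort surface is the natural reading of that requirement. Density is a
Gaussian product-kernel KDE evaluated on a 400 × 400 grid over the data
bounding box padded by 0.4° per side, computed in raw geographic degrees.
At ~32° N a degree of longitude is ~15 % shorter than a degree of latitude,
so the kernel is mildly anisotropic in metric terms; an equidistant
projection option exists for users who care.

The bandwidth matrix is a two-stage diagonal plug-in estimator: a
normal-scale pilot g_j = σ_j·n^(−1/10) feeds kernel estimates of the
fourth-order integrated density derivatives ψ40, ψ22, ψ04 (Hermite forms,
self-pairs included; pairwise sums subsampled to ≤ 1500 points for O(n²)
control), and the AMISE surrogate

    1/(4πn·h1·h2) + (h1⁴ψ40 + 2h1²h2²ψ22 + h2⁴ψ04)/4

is minimized over (h1, h2). The flatter-than-classical pilot rate was
chosen because the self-pair terms otherwise dominate the ψ estimates at
the n ≈ 5000 scale this pipeline sees; with it, the estimator reproduces
the closed-form Gaussian ψ values within ~10 % and approaches the
normal-reference bandwidth n^(−1/3)σ² on Gaussian data. Exact numerical
agreement with any specific published plug-in implementation is not
promised; correctness is asserted through the reference-rule limit and
scale-equivariance property tests. On failure (non-positive curvature
estimates) the estimator degrades to the normal-reference rule with a
warning.

The p % core range is the highest-density region: grid cells sorted by
density descending, mass accumulated to p, threshold set at the last
included cell, mask = {density ≥ threshold}. An individual is excluded
when its fix nearest to landfall falls outside the 25 % mask ("outside
core range") or when its fixes do not span the study window ("incomplete
coverage"); a window-overlap membership test is available behind a flag.

## EMbC

The behavioral clusterer is a four-component Gaussian mixture over
(velocity, turning angle) anchored to the binary quadrant structure.
Initialization is deterministic: delimiters start at the marginal medians
and components at quadrant-conditional moments (an empty quadrant is
reseeded at the global moments with weight 10⁻³). After every EM iteration
components are relabelled so the two lowest-speed components carry the L
velocity bit and, within each speed pair, the lower-turn component carries
the L turn bit; the log-likelihood is asserted non-decreasing at every
iteration (tolerance 10⁻⁸). After convergence (relative log-likelihood
change < 10⁻⁹) the per-variable delimiters are recomputed once, as the
equal-likelihood crossing of the weighted low-group vs high-group marginal
Gaussians between the group means (midpoint fallback when no crossing
exists). Labels are argmax-posterior; delimiter-quadrant labels are
exported alongside because the two labelings legitimately disagree near
boundaries. No per-fix uncertainty weighting is applied: GPS error of
~4 m is negligible against 90-min steps.

Smoothing favours homogeneous behavioral bouts: in a single forward pass,
any fix whose two temporal neighbours (within the same burst) share a label
different from its own has its posterior for that label multiplied by w
(default 2; w = 1 disables smoothing) and is reassigned if the boosted
posterior wins. The left neighbour reflects flips already made in the
pass, which makes the pass idempotent on alternating single-point
patterns. Runs of length ≥ 2 of a minority label are provably never
altered. The magnitude of the likelihood boost in the original description
of this procedure is not published, so w is an exposed parameter rather
than a claimed ground truth.

Pooling maps LL → inactive and LH/HL/HH → active. Activity budgets are
computed per individual first and then averaged (mean ± sample SD), so the
cohort active and inactive percentages need not sum to exactly 100 after
rounding.

## Anomaly runs and the study window

An anomalous hour has a pressure reading ≥ 1 monthly SD from the monthly
mean (sample SD over non-missing hours). The criterion is two-sided by
default — the source description does not state a direction — with a
low-side-only mode since cyclones are pressure dips; wind is never used
for anomaly screening. Maximal contiguous anomalous hours form runs; any
non-anomalous or missing hour breaks a run. The cyclone run is the run
containing the monthly pressure minimum, unless an explicit landfall hint
overrides it. The study window runs from the end of the latest run
strictly before the cyclone run (month start if none) to the start of the
earliest run strictly after it (month end if none). Fix–weather matching
minimizes |Δt| with ties to the earlier record; pairs more than 90 min
from any record are dropped with a warning.

## State regression

The multinomial logit is fitted by damped Newton–Raphson on the full
(K−1)·p observed information, with the inactive state as the reference
level; with the two pooled states used here it reduces exactly to binary
logistic regression, and the implementation is cross-checked against an
independent IRLS fit to 10⁻⁶. Convergence requires max |score| < 10⁻⁸ or
relative log-likelihood change < 10⁻¹⁰; a coefficient-norm guard reports
perfect separation, and rank-deficient designs fail with the collinear
columns named. Standard errors are inverse-observed-information; t-values
use a two-sided normal reference (the reference distribution is not stated
in the source reporting convention, so normal is used and documented).

Covariates are z-standardized within the event window by default: the
published coefficient magnitudes (intercepts 0.37–1.00, slopes 0.09–0.26)
are consistent with standardized, not raw-kPa/raw-km/h, predictors — the
source never states the scale, so this choice is surfaced prominently and
a raw-scale mode exists. Model selection uses AIC = 2k − 2 logLik (AICc
optional), with ΔAIC < 2 flagged as co-best; no model averaging.
"Transition probability" in the output labels means the fitted probability
of the active state with inactive as reference — what a multinomial logit
on states actually yields. Observations are treated as independent across
fixes and individuals; serial autocorrelation is real and unmodelled (no
random effects), which makes the reported SEs anticonservative for
strongly autocorrelated data.

Kruskal–Wallis (tie-corrected, χ² with g−1 df) and Wilcoxon rank-sum
(tie-corrected normal Z, no continuity correction) handle between-event
weather comparisons, with pairwise rank-sum follow-ups only after a
significant omnibus test and no multiplicity adjustment by default (Holm
optional). For small samples — pooled n ≤ 12 (KW) or C(n, n1) ≤ 2·10⁵
(rank-sum) — the p-value switches to exact permutation enumeration,
because the asymptotic approximations are off by far more than any
reasonable tolerance at these sizes (e.g. normal p ≈ 0.08 vs exact 0.2
for samples of 2 and 3).

## Synthetic data

The weather generator emits one calendar month of hourly records: an AR(1)
baseline (mean 101.4 kPa, stationary SD 0.05 kPa, coefficient 0.9) minus a
Gaussian cyclone dip (1.8 kPa deep, 12 h half-width, centred on day 11)
and two minor dips (0.8 kPa on days 4 and 25) that play the role of the
ordinary weather systems bracketing a real study window. Wind is a floored
baseline (~9 km/h) plus a peak proportional to the dip (28 km/h per kPa).
These defaults echo the printed scales of the study system — monthly
pressure ≈ 101.3 ± 0.4 kPa, storm minimum ≈ 99.5 kPa, wind maximum ≈ 60
km/h — and are scenario parameters, not fits. The AR baseline SD is small
because synoptic variability is modelled by the explicit dips; this keeps
the anomaly structure of a realization deterministic up to edge wobble.
The truth record applies the ≥ 1 SD rule to the emitted series inline
(independent of the detector's run-segmentation code) and stores the
anomalous-hour mask and cyclone run bounds.

The track generator is a duty-cycled state-switching random walk for 40
individuals around a colony at (−80°, 32.5°). At each scheduled fix,
P(active) = inv-logit(0.6 + 0.25·z_bp − 0.20·z_wv) on month-standardized
weather; active substates follow a 3×3 Markov matrix. State kinematics
(mean speed km/h / turn centre / wrapped-Cauchy concentration): inactive
0.15 / 0 / 0.7, localized search 2.5 / π / 0.4, commuting 12 / 0 / 0.85,
dispersive search 10 / π / 0.35 — satisfying the ordering inactive <
localized < dispersive ≤ commuting, with gamma(shape 4–6) speed draws and
overlap allowed in the tails. Steps advance positions with the spherical
destination formula; across duty-cycle gaps the effective step duration is
capped at 4 h so dormant periods do not produce implausible displacement.
A soft tether redirects birds toward their home centre beyond 40 km,
emulating central-place range fidelity. During deep pressure anomalies
(z_bp ≤ −1) birds shelter at a shared coastal refugium near the colony:
inactive birds hold position exactly, active ones make short localized
flights around it — the spatial expression of the sheltering behavior the
pipeline is designed to detect, and the mechanism that places every
main-cohort bird inside the 25 % core range at landfall. Eight "absentee"
individuals live ~500 km poleward for the whole month and shelter there,
providing the planted exclusions (40 simulated → 32 analyzed by
construction). The generators are pure functions of (config, seed).

What the generator does **not** emulate: positional (Argos/GPS) error,
tides and diel cycles in movement, heterogeneous per-bird coupling to
weather, spatially-varying storm exposure (one shared station series
forces identical covariates on all birds, as the single-station design of
the original analysis does), and habitat structure. Passing tests
therefore certify the pipeline's statistical machinery — unit handling,
windowing, clustering geometry, regression numerics, planted-design
recovery — not the ecological fidelity of any particular real dataset.

## Problem sizes used in validation

The regression oracle check uses 20 datasets of n = 500; the
coefficient-recovery study 200 replicates of n = 3000 (bias < 0.05,
95 % CI coverage in [0.90, 0.99]); EMbC recovery the documented
4 × 500-point separable scenario; core-range calibration 5000 bivariate
normal draws on the full 400-cell grid; cohort retention the default
40-bird month (~3900 fixes). These sizes make the whole battery run in
tens of seconds while keeping Monte-Carlo error well inside the asserted
tolerances.

## Known limitations

- EMbC here fixes internals (no per-fix uncertainty weights, one
  post-convergence delimiter refinement) that published implementations
  leave unstated; numerical identity with them is not claimed.
- The KDE core range is computed in degrees; metric anisotropy at
  temperate latitudes slightly distorts the region relative to a projected
  analysis.
- Independence assumptions in the state regression understate uncertainty
  for autocorrelated fix series.
- The four-model AIC set inherits the collinearity of pressure and wind
  during a storm: single-covariate odds ratios from co-best models should
  be interpreted jointly, not in isolation.
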