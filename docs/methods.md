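# Methods

This note records the statistical model, the concrete algorithmic choices,
and the limits of what the test suite demonstrates. It is written for users
who want to know exactly what the package computes.

## Observation model

Samples `Y_1..Y_n` at rate `f_s` follow

    Y_i = (F_m * f)(i/f_s) + eps_i,

with `f` piecewise constant (levels `c_j`, change times `tau_j`) and `eps` a
centered stationary Gaussian sequence obtained by passing white noise through
the truncated filter kernel: its autocorrelation `rho(0..m)` is the
normalized overlap integral of the kernel with itself at integer sample
lags, and `rho(h) = 0` exactly for `h > m`. The noise level `sigma` is
parameterized as the **post-filter marginal SD** (`rho(0) = 1`): that is the
quantity a user estimates from quiet stretches of already-filtered data, and
it absorbs the white-noise scaling convention that the continuous-time model
leaves implicit. In the heterogeneous regime `sigma(.)` is a step function
with jumps only at the `tau_j` (open-channel noise); the sample straddling a
change carries the right segment's level.

## The filter

Only analogue Bessel low-pass filters are supported (the hardware standard).
The impulse response is the partial-fraction sum of exponentials of the
normalized p-pole Bessel transfer function, with the -3 dB point at
`cutoff * f_s` (so cutoff 0.1 at 50 kHz means 5 kHz in the time domain).
All ACF values, the step response, and the convolution of step signals are
computed from this pole/residue representation in closed form — sums of
exponentials — with no quadrature error; the test suite cross-checks against
an independent oversampled-grid quadrature oracle.

Truncation: `m` is the smallest integer such that the *untruncated* kernel's
ACF is below `acf_threshold` (default 1e-3) at **all lags >= m**; for the
4-pole, cutoff-0.1 filter this gives m = 11 (`rho(10) = 1.35e-3`,
`rho(11) = 8.3e-4`). The truncated kernel is renormalized to unit integral,
so constants are preserved by convolution and the step response reaches
exactly 1 at `m/f_s`. The kernel is causal; no zero-phase correction is
applied, so a change at `tau` produces a ramp on `[tau, tau + m/f_s]`. The
4-pole Bessel step response over- and undershoots by about 0.8%; several
design choices below exist to cope with exactly that.

## Colored-noise simulation

The simulator represents the noise as an MA(m) process whose m+1 weights come
from spectral factorization of the band covariance `rho(0..m)` (roots of the
covariance generating polynomial inside the unit circle). The simulated
noise is exactly stationary with exactly the model ACF at every lag — not
asymptotically, which matters because the Monte-Carlo calibration of every
critical value runs on these traces. One integer master seed drives
everything; independent streams are spawned per repetition.

What the generator does *not* emulate: 1/f and f^2 noise components,
baseline drift, and recording artifacts. Passing error-control tests on
simulated data therefore demonstrates correctness *under the model*; on real
recordings the error level is approximate, and the robust (median-based)
noise estimators are the main line of defense.

## Multiscale detection

**Interval system.** All intervals whose lengths lie on a dyadic grid
(factor 2) at every position, plus the full-trace interval. The
above-filter-length detector starts the grid at `m + 2` and drops the first
`m` samples of every interval (ramps cannot contaminate retained samples);
the all-scale detector starts at 1 and drops nothing. The heterogeneous
variant starts at `3(m+1) + 1` so each interval retains at least `m + 3`
lag-(m+1) differences — studentizing with fewer makes the null statistic's
tail explode and costs all power. A full O(n^2) system would not change the
error-control contract, because calibration always runs on the *same* system
as detection; the dyadic grid keeps run time near-linear per scale.

**Statistic.** For an interval of length `l` with `k` retained samples and
candidate level `c`:

    T_I = |mean(Y_retained) - c| / (sigma_I * sd_k) - sqrt(2 log(e n / l)),

where `sd_k = sqrt(Var(mean of k consecutive unit-SD colored samples))` from
`rho`, and the additive penalty is the standard multiscale scale balance.
`sigma_I` is the global noise level (homogeneous) or an interval-local
robust scale (heterogeneous): the rolling median of |lag-(m+1) differences|
inside the interval, scaled to an SD. Robustness here is not cosmetic — a
moment-based interval variance is inflated by any jump inside the interval
and masks the very event being tested.

**Fit.** The returned idealization has the minimal number of jumps such that
some level per segment satisfies every interval constraint at the calibrated
critical value; equivalently, per candidate segment the intersection of the
per-interval confidence bands must be non-empty. A dynamic program over
segment ends finds it (quadratic in `n`; intended problem sizes are up to a
few tens of thousands of samples per call). Ties among equal-jump-count fits
are broken by least squares of the segment means. Segment levels are the
means of the post-ramp samples. Brute-force enumeration on all instances
with n <= 40 verifies the DP in the test suite.

**Error control.** Critical values are empirical "higher" quantiles of r
simulated null maxima (defaults: r = 10,000; 1,000 for the two-stage
method; minimum 100 enforced). Since the true constant satisfying all
constraints is a subset event of "some constant satisfies all constraints",
the probability of any false-positive change on model-conform data is
*bounded* by alpha — the observed false-positive fraction on pure noise runs
below the nominal level (conservative), while the exceedance probability of
the calibrated statistic itself matches alpha exactly (both are tested).

## Short events

**All-scale detector with postfilter.** With scales down to single samples,
an abrupt change is resolved as a staircase of incremental steps along the
convolution ramp. The postfilter (the concrete rule is this package's own
formalization) iterates two passes to a fixpoint: (i) collapse every maximal
run of >= 2 consecutive changes that is monotone in level with intermediate
segments shorter than `m` samples into a single change at the run's first
change; (ii) remove ringing micro-steps — changes whose amplitude is below
5% of an adjacent change within `2m` samples, merging the two segments with
duration-weighted levels. Pass (ii) exists because the Bessel over/undershoot
(~0.8%) survives pass (i) as a tiny counter-directional step; 5% sits safely
between ringing (< 1% of the neighboring jump) and genuine subconductance
events (comparable to their neighbors). The combined operation is
idempotent. Homogeneous noise only.

**Two-stage detector.** Stage 1 runs the above-filter-length detector at
level alpha1 (default 0.01). Stage 2 tests, inside each fitted segment,
every window of each length `l` in the scale set (default 1..20; chosen so
local tests cover peaks up to about two filter lengths, beyond which stage 1
detects reliably):

    |mean(window) - c_segment| / (att(l) * sigma_seg * sd_l)  >  q_l,

where `att(l)` is the kernel-attenuation factor — the maximal mean response
of a convolved unit peak of length `l` over an `l`-window, maximized over
the peak's sub-sample phase on a 1/100-sample grid — so the statistic
estimates the *unattenuated* peak amplitude in noise units. Per-scale
critical values split alpha2 (default 0.04) equally across the scale set
(Bonferroni within the local tests) and are calibrated by Monte Carlo on the
same window geometry. Windows start `m` samples after the segment's left
edge and end `m` clear of its right edge (a late-placed stage-1 boundary
would otherwise leak its ramp into trailing windows); significant windows of
one scale within `m` samples of each other are merged (keeping the
strongest), and across scales the smallest significant scale wins. Accepted
windows become peak candidates: two changes with an attenuation-corrected
middle level. Stage-1 changes are always a subset of the output; the overall
error level is approximately alpha1 + alpha2.

## Local deconvolution

Events are classified by spacing: changes closer than the isolation distance
— 3 filter lengths (homogeneous) or 5 (heterogeneous) — form groups. A
single change or an isolated pair (peak) is refined by least squares against
the exact convolved step model over a window reaching to the neighboring
events minus a buffer (`2m + 1` samples beyond the previous change, `m + 1`
before the next). Change times are searched by three-stage grid refinement
to a final resolution of `(1/100)/f_s`; at each candidate time the levels
are the closed-form least-squares solution. The pair search uses wide,
asymmetric coarse ranges (down to `m/2 + 2` samples left, up to `m + 1.5`
right of the grid positions) because detection systematically offsets a
peak's falling edge — toward the convolution maximum for short peaks, toward
the overshoot-decay onset for longer ones. The grid-aligned time is always a
candidate, so the refined fit's residual sum of squares never exceeds the
grid fit's. In the heterogeneous regime residuals are weighted by the
segment noise levels, transition samples by the right segment's.

Groups of >= 3 changes are left at grid resolution; the segments between the
group's first and last change are flagged `no_deconvolution` and a warning
is raised. Exports can blank them. Deconvolution never changes the number
of changes.

On noise-free forward-simulated data the recovery is essentially exact:
change times to 0.005 samples and amplitudes to 0.5% for peaks from 2
samples (0.18 filter lengths) upward — comfortably inside the 1/(100 f_s)
and 1% targets the tests assert down to 0.3 filter lengths.

## Noise estimation

Global and per-segment noise levels use lag-(m+1) differences (uncorrelated
under the truncated-kernel model, SD `sigma * sqrt(2)`) reduced by a
median-absolute-deviation scale: insensitive to the conductance jumps the
differences straddle and to gross artifacts (1% contamination of 100 sigma
moves the estimate by < 10%). Per-segment estimates drop the first `m` ramp
samples; segments too short for two differences inherit the nearest
neighbor's estimate and are flagged.

## Downstream analysis

Event histograms (one entry per fitted segment) and amplitude histograms
(consecutive level differences) visualize the conductance states; fitted
levels form a mixture around the true states that is *narrower* than the raw
point-amplitude histogram, since each level averages many samples. The half
sample mode estimates each state robustly: repeatedly keep the
ceil(k/2)-point contiguous window of the sorted sample with the smallest
range (leftmost on ties) until <= 3 points remain; for three points the mean
of the closer pair (middle on a tie), else the mean. Level assignment maps
each segment's level into user-supplied disjoint intervals, leaves outliers
unassigned (typically artifacts), and merges consecutive same-state segments.
Dwell times per state are fitted by the left-truncated exponential MLE
`rate = 1/(mean(d) - t0)` over dwells `d >= t0`; the truncation limit
(default 3 samples in the CLI) is a crude guard against missed short events,
not an exact missed-event correction — events below the detection resolution
also *merge* neighboring dwells, a bias truncation cannot remove. The lag-1
Pearson correlation of consecutive dwells screens the Markov independence
assumption.

## Numerical and interface conventions

* Times in seconds, conductance in nS; sample `i` (1-based) at `i/f_s`.
* Segments are half-open `[leftEnd, rightEnd)`; a grid change at sample
  index `k` (0-based) stands for a true change in `(k/f_s, (k+1)/f_s]` and
  is represented by the midpoint until deconvolution refines it.
* Exports drop the first and last segment by default (their true extent is
  not identifiable from the window); a flag keeps them.
* Critical-value cache: one self-describing JSON file per key
  (statistic family, n, filter fingerprint, scale set, r); corrupted entries
  trigger a warning and deterministic re-simulation. Quantiles use the
  conservative "higher" rule (the interpolation rule is a convention).
* DP feasibility uses an absolute tolerance of `1e-9 * max(1, range(Y))` so
  noise-free data (bands of zero width) behave exactly.
* Equidistant sampling is enforced on input to 1e-6 relative step deviation.

## Problem sizes and determinism

Default test and acceptance runs use traces of n = 1,024–16,384 samples,
calibrations of r = 100–1,000 repetitions and 400–1,000 fresh replicates
per error-control check; these sizes give binomial/Monte-Carlo standard
errors well below the asserted margins while keeping a full run in minutes.
Every stochastic step — simulation, calibration, fresh-replicate draws — is
driven by explicit integer seeds, and the full pipeline (trace, config,
seed, cache) → fit is bit-reproducible.

## Known limitations

* FWER control is exact-by-construction only for the implemented interval
  systems and conservative overall; no claim of bitwise agreement with other
  implementations of these method families.
* The local short-event test is mean-based with attenuation correction; a
  likelihood-ratio test over exact peak templates could be more powerful for
  1–2-sample events.
* Clusters of >= 3 close changes are not deconvolved (flagged instead); in
  recordings dominated by such clusters ("extreme flickering"), methods
  based on conductance-distribution fitting are more appropriate.
* The DP is quadratic in n; million-sample traces should be processed in
  windows.
* Varying-voltage experiments and non-Bessel filters are out of scope.
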