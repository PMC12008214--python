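# Methods

This note documents the models, parameter choices and numerical decisions
behind `tremorcam`, and what the synthetic experiments do and do not show
about real recordings.

## Amplitude estimation

The estimator decomposes the fingertip path into *swings* between motion
reversals and reports the median swing path length.

Order of operations.  The 2–10 Hz band-pass is applied to the per-axis
*positions*, not to the displacement magnitude: the displacement magnitude
of an f-Hz tremor oscillates at 2f, which already leaves the band for
tremor above 5 Hz, so filtering the displacement would suppress the very
signals the band is meant to keep.  Turning points are detected on the
displacement of the filtered positions (zero-phase filtering preserves
their timing); the swing sums always use the displacement of the raw,
unfiltered positions, so the amplitude estimate is not attenuated by the
filter.

Turning-point rule.  A sample is a turning-point candidate when it is
strictly below its left neighbour and not above its right neighbour (the
non-strict right side resolves plateaus deterministically).  Candidates are
accepted smallest-value first, index breaking ties, subject to a minimum
separation of `fs / (2·f_high)` samples — half a cycle of the fastest
passband tremor — which suppresses noise-induced double minima.  Endpoints
are never turning points.

Degenerate-input guard.  Turning points are only searched when the filtered
displacement is genuinely modulated: its p5–p95 spread must exceed 0.2× the
90th percentile of the raw displacement.  Monotone drift fails this test
(its only in-band content is filter edge leakage, measured at ~8% of the
step size for the 4th-order design), as does constant-speed motion, whose
displacement magnitude carries no modulation; both are reported "not
estimable" instead of being sliced at numerical ripple.  Genuine tremor,
and even pure tracking jitter, passes comfortably (band-limited jitter
retains ≈0.4 of the raw step scale).

Sub-sample reversal correction.  The two displacement samples bounding a
swing straddle the reversal.  Summing whole samples across a reversal
systematically under-measures the path, and when the sampling grid is
phase-locked to the tremor (e.g. exactly 8 Hz at 120 Hz) the *median* swing
sits on a biased mode several percent low.  Each boundary step is therefore
split at a sub-sample estimate of the reversal point: a least-squares
parabola through the (up to) four samples around the fold, with the vertex
time taken from the samples' projection onto their local principal motion
direction.  The principal-direction projection makes the estimate exactly
rotation- and scale-invariant; the residual bias on noiseless sinusoids is
below 0.15% across 4–8 Hz.  Without position data the correction degrades
to splitting the fold displacement evenly.

Gap handling.  Undetected runs up to 0.25 s are linearly interpolated
(short enough that a 2 Hz tremor cannot reverse unseen more than once);
longer runs split the trace into segments analyzed independently, and
swings are pooled across segments before the median.  Interpolating across
long gaps would fabricate amplitude.

Units.  Metric traces are analyzed in millimetres (metre-scale traces
converted on the fly).  Pixel and normalized traces are scaled through the
imaged fiducial marker (9.5 mm diameter): mm/px factors are computed per
axis and applied componentwise before the Euclidean norm.  Without a
calibration these traces are analyzed in their native units, as in purely
virtual experiments.  Median ties (even swing counts) take the mean of the
two central values.

## Peak-frequency estimation

Per-axis Welch spectra of the band-passed positions use a Hann window, 10 s
segments, 50% overlap and 4× zero-padding — ≈0.025 Hz grid spacing at
120 Hz input.  Zero-padding is the simplest spectral interpolation that
supports the sub-0.1 Hz frequency errors this method is expected to deliver
on 30 s recordings; it sharpens peak *location*, not resolution.  Axis
spectra are combined by averaging, which is robust to viewpoint-dependent
dominance of one axis (the best-axis alternative is brittle when the
dominant axis is the noisiest).  Camera-derived traces contribute x/y only
— the estimated depth channel is too noisy to help — while motion-capture
and accelerometer series use all three axes.  A peak must lie inside the
3–8 Hz frequency-of-interest band and reach 10% of the spectrum's global
maximum; otherwise the result is *absent*, which is a value, not an error.
Traces with under 25% of frames detected are reported absent outright.

## Synthetic scene model

The hand is a fixed splayed 21-landmark template (package constant, palm in
its local x/y plane) that translates rigidly: articulated finger motion is
not simulated because the analysis reads a single landmark of a shaking
hand.  The tremor displacement is `env(t)·sin(φ(t))` along a unit axis,
with a linear amplitude envelope and a phase that accumulates optional
cycle-to-cycle frequency jitter; a sinusoid is the minimal model consistent
with a single spectral peak.  Default conditions mirror the validation
setting: 30 s at 120 Hz, camera at 1.5 m, 1920×1080 with a 1500 px focal
length, default viewpoint 45° above the hand, tremor along the palm normal.

Camera and tracking noise.  Projection is an ideal pinhole after rotating
the camera about the hand's rest centroid on an azimuth/elevation grid
(15° steps over a half-sphere by default).  Per-frame detection confidence
is `clip(c₀·|cos θ|^γ + ε, 0, 1)` with θ the angle between palm normal and
viewing direction, c₀ = 0.95, γ = 2, ε ~ N(0, 0.05); frames below 0.3 are
undetected.  Only the qualitative pattern — tracking degrades toward
frontal, in-palm-plane views — is anchored in observed behaviour of hand-
pose frameworks; the functional form is a modelling choice.  Landmark
jitter is AR(1)-correlated in time (ρ = 0.8, marginal sd 0.5 px in the
image plane, 2 mm for metric outputs): tracking noise on video is strongly
frame-to-frame correlated, and white jitter would let the path-length
estimator's noise floor dominate unrealistically.

Depth ("2.5D") emulation.  The normalized trace carries a pseudo-depth
channel: true depth deviation on the x-pixel scale, with 3× the landmark
jitter and slow multiplicative scale noise (cv 10% at ~1 Hz knots).  The
metric "world" trace is the hand trajectory about its rest centroid,
re-expressed in *camera-aligned* axes in metres with the same slow scale
noise: camera alignment matches the convention of 2.5D hand-pose outputs,
and centring on the rest pose (rather than per frame) preserves the rigid
tremor translation the analysis must see.

References.  The OMC-like trace holds three fiducial landmarks (thumb tip,
middle MCP, middle tip) resampled to 100 Hz with 0.05 mm white noise.  The
IMU is the palm centroid resampled to 200 Hz by cubic spline — a C²
interpolant is required because acceleration is a second difference —
differenced, plus the 9.81 m/s² gravity reaction and white noise
(0.1 m/s²).  The marker's imaged extent is rounded to whole pixels, as a
pixel measurement would be, so calibration carries realistic quantization
error (~5% at the default geometry).

Severity scores.  Synthetic cohorts draw peak-to-peak amplitudes
log-uniformly (perceived severity is logarithmic in amplitude) and map them
to ordinal 0–5 scores through configurable thresholds (1/10/30/100/200 mm
band edges, half-point scores at geometric midpoints).  These thresholds
are a package approximation of clinical performance-item anchors, not a
published table; rest and postural tremor use the same map.

What the simulator does not emulate: articulated or rotational hand
motion, non-sinusoidal and re-emergent tremor, lighting/occlusion effects,
rolling shutter, soft-tissue marker motion, IMU orientation drift, and any
actual behaviour of a specific tracking network.  Passing tests therefore
demonstrate that the *pipeline* is correct and that its viewpoint geometry
and noise trade-offs behave as modelled — not that any particular
framework achieves a given accuracy on patients.

## Experiments and problem sizes

The angle sweep simulates one 30 s scene per grid cell (13×7 cells at 15°;
tests and the acceptance checks use a 30° grid, 7×4 cells) and scores mean
confidence (undetected frames as 0) and uncalibrated log median amplitude;
cells with under 20% detection or no band-limited oscillation report
amplitude absent.  The ramp experiment uses 0→20 mm at 6 Hz and correlates
z-scored per-swing amplitudes against the true envelope at swing times.
The synthetic cohort uses n = 20 subjects, amplitudes 1–100 mm peak-to-peak,
frequencies 3.5–7.5 Hz, one scene each.  All runners are deterministic
given their seed (per-cell/subject seeds derive from a seed sequence) and
emit machine-readable reports.

## Statistical choices

Kendall's tau-b with tie-adjusted asymptotic two-sided p-values throughout;
at cohort sizes near 20 the normal approximation is adequate and exact
permutation adds nothing.  Group comparisons screen paired differences with
Shapiro (α = 0.05) to choose between the paired t-test and the Wilcoxon
signed-rank test; more than two methods use Friedman.  Amplitude errors are
reported absolute (mm) and relative (% of reference); logs are natural,
with no offset since amplitudes are strictly positive by construction.

## Known limitations

Amplitude estimates from camera-derived traces are geometry-bound: they
measure the image-plane component of the motion, so a single uncalibrated
viewpoint underestimates out-of-plane tremor, and the systematic-error test
will flag exactly this on cohorts with varied amplitudes.  The median swing
statistic saturates at the jitter noise floor for sub-millimetre tremor.
The pipeline assumes an essentially stationary tremor axis over a
recording; slow axis rotation smears swing amplitudes but not frequency.
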