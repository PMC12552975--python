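# Methods

This note documents the models, numerical choices and limitations behind
`i4dsim`. The package simulates the measurement chain of a prospective
breathing-gated sequential 4DCT study — surrogate signal acquisition,
latency compensation, gated beam control, and 20-bin motion reconstruction —
and evaluates it with the standard signal-agreement and COM-deviation
analyses.

## Breathing and motion model

The regular breathing model is ζ(t) = A_p2p · cos⁶(πt/T_cycle). The cos⁶
shape gives the physiologically typical long quiescent end-exhale plateau
and sharp inhale peaks. We use the argument πt/T_cycle so that exactly one
breathing cycle spans `T_cycle` and BR = 60/T_cycle holds by construction
(the cos⁶ form is sometimes written with 2πt/T, which halves the period and
is inconsistent with that BR definition; we adopt the convention that makes
the two consistent). Phase origin: t = 0 at an end-inhale peak; the exhale
plateau sits at amplitude 0.

Sinusoids ζ(t) = A_p2p · sin(2πt/T_cycle) are used for latency measurement
runs. Note the printed convention: the sine coefficient is `A_p2p`, so the
sinusoid's excursion is ±A_p2p.

Irregular breathing draws per-cycle amplitude and period independently from
uniform ranges (defaults: the clinically observed 5–25 mm and 6–20 BPM
spans); each cycle is a sin⁶ arch from end-exhale up and back, so cycles
join continuously (C¹, since the derivative vanishes at the joins). A
uniform per-cycle draw was chosen because the study conditions specify
ranges, not a stochastic process; anything smoother (e.g. an AR process on
cycle parameters) would add unconstrained assumptions.

Sudden-stop interruptions hold the amplitude constant for a dwell (default
1 s — brief, but long enough to isolate the following maximum as a
reference point) and resume phase-continuously, i.e. the remainder of the
waveform is delayed by the dwell.

Tumor trajectories are the baseline-normalized surrogate waveform scaled
per axis (S–I/A–P/L–M) — phantom platform and insert are mechanically
coupled, so internal and external motion are perfectly correlated. Real
patients show internal–external phase shifts and hysteresis; this simulator
deliberately excludes them, because the measurand of interest is the error
introduced by the *surrogate chain*, not by internal correlation.

Couch travel is a staircase of fixed increments (nominal
0.9 × 64 × 0.6 mm = 34.56 mm) with smooth cosine ramps (default 0.8 s per
step; the ramp shape is not critical and is configurable).

## Surrogate measurement chain

Measured signal: s(t) = scale · ζ(t − latency) + offset +
coupling · d_table(t) + ε, with white Gaussian ε. Latency is applied as an
interpolated time shift so sub-sample delays (e.g. 45.9 ms on a 20 ms grid)
are representable. The noise spectrum of real optical trackers is not
white, but no spectral data were available; the noise model is a
configurable hook.

Couch contamination enters additively in amplitude through a single
coupling coefficient (default 1 for the surface preset, 0 for the marker
preset): surface tracking is perturbed when the couch carries the
patient/phantom, marker tracking by a couch-mounted camera is not. The
correction model advances by a *fixed* 34.5 mm per detected step, so with a
true 34.56 mm increment a residual of 0.06 mm per completed step
accumulates — negligible over a few steps, linearly growing for long scan
ranges.

Presets: `surface` (latency 63 ms, noise SD 0.1 mm, couch-coupled) and
`marker` (23 ms, 0.05 mm). The latencies are the absolute end-to-end values
measured for the two system classes; the noise SDs are chosen so that the
preprocessed marker signal reproduces its reported sub-0.2 mm RMSE / r=1.0
quality while the surface signal is visibly noisier.

The predictor is a causal sliding least-squares polynomial extrapolation:
at each sample, fit order-p (default 2) over the trailing window (default
0.3 s, ~1/10 cycle) and evaluate at t + horizon. On a uniform grid this
reduces to a fixed FIR kernel, computed once via the pseudoinverse of the
window Vandermonde matrix. The vendor algorithm behind the real system is
proprietary; quadratic-over-0.3 s balances tracking lag against noise
amplification and is fully configurable. Measured behavior: a 50 ms horizon
advances a cos⁶ signal by ~57 ms (slight overshoot from the curvature of
the extrapolated harmonics) with ~0.1 mm waveform distortion at 15 mm
amplitude, preserving r ≥ 0.999.

## Preprocessing

Traces are resampled to 20 ms, truncated to [first X-ray-on − 20 s, last
X-ray-on + 10 s], smoothed with a centered 100 ms (5-sample) moving average
(window shrinks symmetrically at the edges — no padding bias, zero group
delay), and baseline-normalized by subtracting the minimum between the
first two local maxima. Temporal alignment maximizes integer-shift
normalized cross-correlation within ±2 s (ties toward smaller |lag|);
latency analyses bypass alignment, since there the shift is the measurand.
The alignment method itself is a design choice — simple, robust for
periodic signals, quantized to the sample grid.

Cycle detection uses prominence-gated extrema (prominence ≥ 0.2 of the
signal span, spacing ≥ 0.5 s); both thresholds reject noise ripples at the
5–25 mm amplitudes of interest and are configurable. Because the cos⁶
end-exhale is nearly flat, the raw argmin jitters under noise; each
extremum time is therefore refined to the midpoint of the contiguous
near-extremal plateau (within 5 % of span), which is stable under noise and
coincides with the analytic extremum for symmetric waveforms. BR = 60 /
mean maximum-to-maximum interval. Inhalation runs minimum → maximum,
exhalation maximum → minimum; only complete min–max–min cycles are
segmented.

Re-running the pipeline on its own output is stable: resampling,
truncation and normalization are idempotent, and the only non-idempotent
stage (the moving average) perturbs an already-smoothed breathing signal by
well under 0.05 mm.

## Latency estimation

Per run, the first local maximum after each sudden stop is located in test
and reference traces, and its time is refined by a linear least-squares
sinusoid fit (free amplitude/phase/offset at the known or estimated cycle
frequency) over one cycle centered on the coarse peak. Relative latency =
mean over stops of (test − reference) peak time, aggregated mean ± SD over
runs. Because both traces are the same waveform up to a shift, any
deterministic bias of the fit cancels exactly in the difference; noise only
adds variance. This recovers sub-sample delays (5–100 ms) with ≤ 2 ms bias
at 0.1 mm noise over 10 runs. Absolute latency = relative + the reference
tracker's baseline delay (16.6 ms, treated as a deterministic constant; its
±1 ms uncertainty is not propagated, matching the point values reported
for such systems). The SD is reported per run (whether reported SDs in
comparable studies reflect per-stop or per-run variation is ambiguous; we
chose per-run).

## Gated acquisition and virtual reconstruction

The beam controller is a documented simplification of the proprietary
prospective gating algorithm: at each couch position, trigger at the first
detected cycle-start minimum of the real-time surrogate, keep the beam on
until the observed cycle has completed plus one gantry rotation (default
0.5 s, configurable — not published for the real system), then move the
couch (0.8 s). This reproduces the essential behavior (beam-on ≈ cycle +
rotation, extension under cycle lengthening) without claiming equivalence
to the vendor's completeness criterion.

Reconstruction is virtualized: no projections or images are formed. Each
beam-on sample is binned from the surrogate — PB: phase fraction within its
min-to-min cycle × 20; AB: per-cycle normalized amplitude decile, split by
direction (10 exhale bins Exh100…Exh10 descending, 10 inhale bins
Inh10…Inh100 ascending, with Inh0 the end-exhale turning point) — and the
per-bin COM is the mean *true* tumor position over the bin's timestamps.
Since binning uses the (delayed, noisy) surrogate while the COM uses ground
truth, surrogate latency manifests directly as COM lag, which is the
mechanism under study. Slab geometry and partial tumor coverage per couch
position are ignored: COM lag arises from surrogate/truth timing, not image
formation.

References: PB — the ideal cos⁶ shape at the 20 bin-center phases (cycle
phased from the end-exhale minimum); AB — amplitude linear in bin index
from full inhale down to full exhale across the exhale bins and back up
(peak-to-peak exactly the axis amplitude). Deviations are measured −
reference, exhale bins multiplied by −1 so positive = lag; repeats (default
3, distinct noise seeds) give per-bin mean ± SD and exhale/inhale group
means. The AB reference's linear-in-index shape differs from the
dwell-weighted bin means of a cos⁶ cycle by up to ~0.03·A per bin; this
bin-wise bias is antisymmetric across the amplitude range and largely
cancels in the signed group means, so group-level deviations are dominated
by residual timing lag (as intended), while per-bin |deviation| means carry
an intrinsic ~0.3 mm floor at 15 mm amplitude.

Measured end-to-end behavior at 20 BPM / 15 mm (S–I, exhale group, AB):
~1.2 mm lag at 63 ms latency without prediction, < 0.1 mm with a 50 ms
horizon, and a sign flip (overcompensation) at 100 ms; PB deviations stay
at or below AB deviations throughout. The full chain at 2 ms sampling
agrees with the 20 ms grid within 0.1 mm on group means.

## Problem sizes and reproducibility

Default study conditions: 120 s signals at 20 ms sampling, 4 couch
positions, 3 repeats per configuration — enough for ~20–40 breathing cycles
and a fully populated 20-bin histogram while keeping any scenario under a
second of compute. All randomness flows from one integer seed through named
`SeedSequence` sub-streams (repeat index, scenario), so reports are
bit-reproducible; derived seeds stay below 2³¹.

## Known limitations

- No internal–external correlation model (phase shift, hysteresis, drift):
  passing tests show the surrogate chain's errors, not surrogate validity.
- No CT image formation; image artifacts, HU fidelity and dose are out of
  scope.
- The predictor and gating rule are generic re-implementations of
  proprietary components; parameter defaults are reasoned choices, not
  vendor values.
- White measurement noise; real tracker noise is colored and
  amplitude-dependent.
- Very low amplitudes (< 5 mm) are untested territory: prominence-based
  extrema detection and amplitude binning degrade as noise approaches
  signal scale.
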