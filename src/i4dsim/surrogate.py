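"""Surrogate measurement chain: latency, gain, noise, couch-motion
contamination, table-motion correction, and polynomial-extrapolation
prediction.

The measured surrogate is modelled as

    s(t) = scale * zeta(t - latency) + offset + coupling * d_table(t) + e(t)

where ``d_table`` is the couch displacement since scan start (surface
tracking of a patch is perturbed when the couch carries the patient through
the gantry) and ``e`` is white Gaussian noise. Table-motion correction
subtracts a modelled couch displacement that advances by a *fixed* increment
per step (34.5 mm in the clinical configuration) regardless of the true
increment, so a per-step model residual of (true - modelled) increment
accumulates linearly with completed steps.

Two presets mirror the systems studied: ``surface`` (absolute latency 63 ms,
noise SD 0.1 mm, couch-coupled) and ``marker`` (23 ms, 0.05 mm, no couch
coupling).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .prep import SignalTrace, from_waveform
from .waveforms import BreathingWaveform, TableProfile, _ramp

#: fixed patch-propagation increment used by the clinical correction model, mm
MODEL_TABLE_INCREMENT_MM = 34.5


@dataclass(frozen=True)
class SurrogateSpec:
    """Measurement model of one surrogate system.

    latency_s        end-to-end delay between motion and reported amplitude
    noise_sd_mm      white Gaussian measurement noise SD
    scale            multiplicative gain (amplitude-to-mm conversion error)
    baseline_offset_mm  additive constant offset
    table_coupling   mm of amplitude error per mm of uncorrected couch offset
    seed             noise stream seed
    """

    latency_s: float = 0.0
    noise_sd_mm: float = 0.0
    scale: float = 1.0
    baseline_offset_mm: float = 0.0
    table_coupling: float = 0.0
    seed: int = 0
    name: str = "generic"

    def __post_init__(self) -> None:
        if self.latency_s < 0:
            raise ValueError(f"latency_s must be >= 0, got {self.latency_s}")
        if self.noise_sd_mm < 0:
            raise ValueError(f"noise_sd_mm must be >= 0, got {self.noise_sd_mm}")
        if not self.scale > 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")


PRESETS = {
    "surface": SurrogateSpec(
        latency_s=0.063, noise_sd_mm=0.1, table_coupling=1.0, name="surface"
    ),
    "marker": SurrogateSpec(latency_s=0.023, noise_sd_mm=0.05, name="marker"),
}


def preset(name: str, **overrides) -> SurrogateSpec:
    """Named surrogate preset, optionally with overridden fields."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class PredictorSpec:
    """Causal polynomial-extrapolation predictor.

    At each time t a least-squares polynomial of ``poly_order`` is fitted to
    the samples in [t - fit_window_s, t] and evaluated at t + horizon_s.
    """

    horizon_s: float = 0.05
    poly_order: int = 2
    fit_window_s: float = 0.3

    def __post_init__(self) -> None:
        if self.horizon_s < 0:
            raise ValueError(f"horizon_s must be >= 0, got {self.horizon_s}")
        if self.poly_order < 0:
            raise ValueError(f"poly_order must be >= 0, got {self.poly_order}")
        if self.fit_window_s <= 0:
            raise ValueError(f"fit_window_s must be > 0, got {self.fit_window_s}")


def apply_surrogate(
    truth: BreathingWaveform | SignalTrace,
    spec: SurrogateSpec,
    table: TableProfile | None = None,
) -> SignalTrace:
    """Measure a ground-truth waveform through a surrogate system.

    The latency is applied as an interpolated (sub-sample) time shift; the
    leading edge holds the first sample value. Deterministic per
    ``spec.seed``.
    """
    trace = truth if isinstance(truth, SignalTrace) else from_waveform(truth)
    t, y = trace.timestamps, trace.amplitudes
    if spec.latency_s >= trace.duration:
        raise ValueError(
            f"latency_s={spec.latency_s} exceeds signal duration {trace.duration}"
        )
    shifted = np.interp(t - spec.latency_s, t, y)
    out = spec.scale * shifted + spec.baseline_offset_mm
    if table is not None and spec.table_coupling != 0.0:
        disp = table.position_at(t) - table.couch_position_mm[0]
        out = out + spec.table_coupling * disp
    if spec.noise_sd_mm > 0:
        rng = np.random.default_rng(spec.seed)
        out = out + rng.normal(0.0, spec.noise_sd_mm, size=len(t))
    return SignalTrace(t.copy(), out, trace.xray_on.copy(), spec.name)


def correct_table_motion(
    trace: SignalTrace,
    table: TableProfile,
    model_increment_mm: float = MODEL_TABLE_INCREMENT_MM,
    coupling: float = 1.0,
) -> SignalTrace:
    """Subtract the modelled couch contamination from a surrogate trace.

    The model reuses the measured step times and ramp shape but advances by
    exactly ``model_increment_mm`` per step; after k completed steps the
    residual contamination is coupling * k * (true - model) increment.
    """
    if table is None:
        raise ValueError("table profile is required for table-motion correction")
    if coupling == 0.0:
        return trace.copy_with()
    t = trace.timestamps
    modelled = np.zeros_like(t)
    for t0 in table.step_start_times:
        modelled += model_increment_mm * _ramp((t - t0) / table.travel_time_s)
    return trace.copy_with(amplitudes=trace.amplitudes - coupling * modelled)


def _predictor_weights(spec: PredictorSpec, dt: float) -> np.ndarray:
    """FIR weights of the sliding polynomial extrapolator on a uniform grid.

    With sample offsets x_j = (j - m + 1) dt relative to the current time,
    the least-squares fit is linear in the data, so evaluating the fitted
    polynomial at +horizon reduces to a fixed convolution kernel.
    """
    m = int(round(spec.fit_window_s / dt)) + 1
    if m < spec.poly_order + 1:
        raise ValueError(
            f"fit window ({m} samples) shorter than poly_order+1={spec.poly_order + 1}"
        )
    x = (np.arange(m) - (m - 1)) * dt
    V = np.vander(x, spec.poly_order + 1, increasing=True)  # (m, p+1)
    P = np.linalg.pinv(V)  # (p+1, m)
    e = spec.horizon_s ** np.arange(spec.poly_order + 1)
    return e @ P  # (m,)


def predict(trace: SignalTrace, spec: PredictorSpec) -> SignalTrace:
    """Causally advance a surrogate trace by the prediction horizon.

    Output timestamps are unchanged; the first ``fit_window_s`` seconds are
    emitted unpredicted (the filter is not yet filled).
    """
    dt = trace.dt
    if dt is None:
        raise ValueError("predict requires a uniformly sampled trace")
    w = _predictor_weights(spec, dt)
    m = len(w)
    if len(trace) < m:
        raise ValueError("trace shorter than the predictor fit window")
    y = trace.amplitudes
    out = y.copy()
    # y_pred[i] = sum_j w[j] * y[i - m + 1 + j]  for i >= m - 1
    out[m - 1 :] = np.convolve(y, w[::-1], mode="valid")
    return trace.copy_with(amplitudes=out)
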