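"""Synthetic breathing waveforms, tumor trajectories and couch-travel profiles.

These generators stand in for the dynamic thorax phantom used to drive
breathing-adapted CT acquisitions: a platform (carrying the external
surrogate) and a spherical tumor insert are mechanically coupled and move
synchronously along a programmed breathing waveform, while the CT couch
steps through the scan range in fixed increments.

Waveform families
-----------------
``cos6``
    The standard raised-power breathing model,
    ``zeta(t) = A_p2p * cos^6(pi * t / T_cycle)``, with one breathing cycle
    per ``T_cycle`` and the quiescent end-exhale plateau at amplitude 0.
    ``t = 0`` sits at an end-inhale peak.
``sinusoid``
    ``zeta(t) = A_p2p * sin(2 * pi * t / T_cycle)``, used for latency
    measurements with sudden-stop interruptions.
``irregular``
    Cycle-wise random breathing: each cycle draws its own peak-to-peak
    amplitude and duration from uniform ranges, and consecutive cycles are
    joined continuously at end-exhale (each cycle is a ``sin^6`` arch from
    0 up to its amplitude and back).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

FAMILIES = ("cos6", "sinusoid", "irregular")

#: axis order used for all 3-D tumor quantities
AXES = ("SI", "AP", "LM")

#: nominal couch increment, mm: 0.9 x (64 detector rows x 0.6 mm collimation)
NOMINAL_TABLE_INCREMENT_MM = 0.9 * 64 * 0.6


@dataclass(frozen=True)
class WaveformSpec:
    """Parameters of a synthetic breathing waveform.

    Parameters
    ----------
    family : {"cos6", "sinusoid", "irregular"}
    a_p2p_mm : float
        Peak-to-peak amplitude of the external surrogate motion, mm.
        Clinically typical values span 5-25 mm.
    t_cycle_s : float
        Breathing cycle duration, s (breathing rate = 60 / t_cycle_s BPM;
        6-20 BPM covers the clinically relevant range).
    duration_s : float
        Total signal length, s. Must cover at least two cycles.
    dt_s : float
        Sampling interval, s (default 20 ms, the common analysis grid).
    a_range_mm, t_range_s : tuple, optional
        Per-cycle uniform ranges (lo, hi) for the irregular family.
    seed : int
        Seed for the irregular family's per-cycle draws.
    """

    family: str = "cos6"
    a_p2p_mm: float = 15.0
    t_cycle_s: float = 4.0
    duration_s: float = 120.0
    dt_s: float = 0.02
    a_range_mm: tuple[float, float] | None = None
    t_range_s: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if not self.a_p2p_mm > 0:
            raise ValueError(f"a_p2p_mm must be > 0, got {self.a_p2p_mm}")
        if not self.t_cycle_s > 0:
            raise ValueError(f"t_cycle_s must be > 0, got {self.t_cycle_s}")
        if not self.dt_s > 0:
            raise ValueError(f"dt_s must be > 0, got {self.dt_s}")
        if self.duration_s < 2 * self.t_cycle_s:
            raise ValueError(
                f"duration_s must cover at least two cycles "
                f"(got duration_s={self.duration_s}, t_cycle_s={self.t_cycle_s})"
            )
        if self.family == "irregular":
            for name, rng in (("a_range_mm", self.a_range_mm), ("t_range_s", self.t_range_s)):
                if rng is None:
                    raise ValueError(f"{name} is required for the irregular family")
                lo, hi = rng
                if not (0 < lo <= hi):
                    raise ValueError(f"{name} must satisfy 0 < lo <= hi, got {rng}")

    @property
    def breathing_rate_bpm(self) -> float:
        return 60.0 / self.t_cycle_s


@dataclass
class BreathingWaveform:
    """A sampled breathing waveform with known extrema.

    ``cycle_boundaries`` holds the analytic extremum times (alternating
    maxima/minima) of the generated signal; downstream code uses them as
    ground truth, independently of any peak detector.
    """

    timestamps: np.ndarray
    amplitudes: np.ndarray
    spec: WaveformSpec
    cycle_boundaries: np.ndarray = field(default_factory=lambda: np.array([]))
    boundary_kinds: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    interruptions: list[tuple[float, float]] = field(default_factory=list)

    @property
    def dt(self) -> float:
        return float(self.timestamps[1] - self.timestamps[0])

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def value_at(self, t) -> np.ndarray:
        return np.interp(t, self.timestamps, self.amplitudes)


@dataclass(frozen=True)
class TumorMotionSpec:
    """Peak-to-peak internal tumor amplitudes per axis (S-I, A-P, L-M), mm.

    The study scenarios are 5/1/1, 15/2/2 and 25/5/5 mm.
    """

    a_si_mm: float = 15.0
    a_ap_mm: float = 2.0
    a_lm_mm: float = 2.0

    def __post_init__(self) -> None:
        for name in ("a_si_mm", "a_ap_mm", "a_lm_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([self.a_si_mm, self.a_ap_mm, self.a_lm_mm], dtype=float)


@dataclass
class TumorTrajectory:
    """3-axis tumor displacement, mm; axes ordered (S-I, A-P, L-M).

    Each axis is the baseline-normalized breathing waveform scaled by that
    axis's amplitude (platform and insert are mechanically coupled).
    """

    timestamps: np.ndarray
    positions: np.ndarray  # shape (n, 3)
    spec: TumorMotionSpec

    def positions_at(self, t) -> np.ndarray:
        out = np.empty((np.size(t), 3))
        for ax in range(3):
            out[:, ax] = np.interp(t, self.timestamps, self.positions[:, ax])
        return out


@dataclass
class TableProfile:
    """Stepwise couch travel: a non-decreasing staircase with smooth ramps."""

    timestamps: np.ndarray
    couch_position_mm: np.ndarray
    step_increment_mm: float
    travel_time_s: float
    step_start_times: np.ndarray

    def position_at(self, t) -> np.ndarray:
        return np.interp(t, self.timestamps, self.couch_position_mm)


def _time_grid(duration_s: float, dt_s: float) -> np.ndarray:
    n = int(round(duration_s / dt_s)) + 1
    return np.arange(n) * dt_s


def generate_waveform(spec: WaveformSpec) -> BreathingWaveform:
    """Generate a breathing waveform from its spec.

    Deterministic given ``spec.seed``. For the regular families the extremum
    times are analytic; for the irregular family they are the per-cycle join
    (minimum) and mid-cycle (maximum) times.
    """
    t = _time_grid(spec.duration_s, spec.dt_s)
    a, T, end = spec.a_p2p_mm, spec.t_cycle_s, spec.duration_s

    if spec.family == "cos6":
        y = a * np.cos(np.pi * t / T) ** 6
        maxima = np.arange(0.0, end + 1e-9, T)
        minima = np.arange(T / 2, end + 1e-9, T)
    elif spec.family == "sinusoid":
        y = a * np.sin(2 * np.pi * t / T)
        maxima = np.arange(T / 4, end + 1e-9, T)
        minima = np.arange(3 * T / 4, end + 1e-9, T)
    else:  # irregular
        rng = np.random.default_rng(spec.seed)
        starts = [0.0]
        amps: list[float] = []
        periods: list[float] = []
        while starts[-1] < end:
            periods.append(float(rng.uniform(*spec.t_range_s)))
            amps.append(float(rng.uniform(*spec.a_range_mm)))
            starts.append(starts[-1] + periods[-1])
        starts_arr = np.asarray(starts)
        amps_arr = np.asarray(amps)
        periods_arr = np.asarray(periods)
        idx = np.clip(np.searchsorted(starts_arr, t, side="right") - 1, 0, len(amps) - 1)
        u = t - starts_arr[idx]
        y = amps_arr[idx] * np.sin(np.pi * u / periods_arr[idx]) ** 6
        minima = starts_arr[starts_arr <= end]
        maxima = (starts_arr[:-1] + periods_arr / 2)
        maxima = maxima[maxima <= end]

    times = np.concatenate([maxima, minima])
    kinds = np.array(["max"] * len(maxima) + ["min"] * len(minima), dtype=object)
    order = np.argsort(times)
    return BreathingWaveform(t, y, spec, times[order], kinds[order])


def inject_interruptions(
    wave: BreathingWaveform, stop_times, dwell_s: float = 1.0
) -> BreathingWaveform:
    """Insert sudden stops: hold the amplitude for ``dwell_s``, then resume
    phase-continuously (the remainder of the waveform is delayed by the dwell).

    ``stop_times`` are on the output timeline. Stops must not overlap.
    """
    stops = np.sort(np.asarray(stop_times, dtype=float))
    if stops.size == 0:
        return wave
    if dwell_s <= 0:
        raise ValueError(f"dwell_s must be > 0, got {dwell_s}")
    t = wave.timestamps
    if stops[0] <= t[0] or stops[-1] >= t[-1]:
        raise ValueError("stop times must lie strictly within the signal")
    if np.any(np.diff(stops) < dwell_s):
        raise ValueError("overlapping stops: consecutive stop times closer than dwell_s")

    # warp output time back onto source time
    tau = t.copy()
    elapsed = 0.0
    src_at_stop = []
    for s in stops:
        src = s - elapsed
        src_at_stop.append(src)
        hold = (t >= s) & (t < s + dwell_s)
        tau[hold] = src
        after = t >= s + dwell_s
        tau[after] = t[after] - (elapsed + dwell_s)
        elapsed += dwell_s
    y = np.interp(tau, t, wave.amplitudes)

    # shift the analytic extrema forward by the cumulative dwell before each
    src_at_stop_arr = np.asarray(src_at_stop)
    bounds, kinds = [], []
    for u, k in zip(wave.cycle_boundaries, wave.boundary_kinds):
        if u > t[-1] - elapsed:
            continue
        shift = dwell_s * int(np.sum(src_at_stop_arr <= u))
        bounds.append(u + shift)
        kinds.append(k)
    return BreathingWaveform(
        t,
        y,
        wave.spec,
        np.asarray(bounds),
        np.asarray(kinds, dtype=object),
        interruptions=wave.interruptions + [(float(s), float(s + dwell_s)) for s in stops],
    )


def generate_tumor_trajectory(
    wave: BreathingWaveform, spec: TumorMotionSpec
) -> TumorTrajectory:
    """Scale the normalized breathing waveform onto the three tumor axes.

    position_ax(t) = A_ax * (zeta(t) - min zeta) / (max zeta - min zeta)
    """
    y = wave.amplitudes
    span = float(y.max() - y.min())
    if span < 1e-9:
        raise ValueError("waveform is flat (zero peak-to-peak); cannot normalize")
    norm = (y - y.min()) / span
    positions = norm[:, None] * spec.amplitudes[None, :]
    return TumorTrajectory(wave.timestamps.copy(), positions, spec)


def _ramp(x: np.ndarray) -> np.ndarray:
    """Cosine ramp: 0 -> 1 over x in [0, 1]."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(x, 0.0, 1.0)))


def generate_table_profile(
    n_positions: int,
    increment_mm: float = NOMINAL_TABLE_INCREMENT_MM,
    travel_time_s: float = 0.8,
    step_start_times=None,
    dt_s: float = 0.02,
    duration_s: float | None = None,
) -> TableProfile:
    """Stepwise couch travel over ``n_positions`` scan positions.

    Each of the ``n_positions - 1`` steps moves by ``increment_mm`` along a
    smooth cosine ramp of duration ``travel_time_s``.
    """
    if n_positions < 1:
        raise ValueError(f"n_positions must be >= 1, got {n_positions}")
    n_steps = n_positions - 1
    if step_start_times is None:
        step_start_times = 2.0 + np.arange(n_steps) * (travel_time_s + 4.0)
    step_start_times = np.asarray(step_start_times, dtype=float)
    if len(step_start_times) != n_steps:
        raise ValueError(
            f"expected {n_steps} step start times for {n_positions} positions, "
            f"got {len(step_start_times)}"
        )
    if n_steps > 1 and np.any(np.diff(step_start_times) < travel_time_s):
        raise ValueError("step start times closer than travel_time_s")
    if duration_s is None:
        duration_s = (step_start_times[-1] + travel_time_s + 2.0) if n_steps else 5.0
    t = _time_grid(duration_s, dt_s)
    pos = np.zeros_like(t)
    for t0 in step_start_times:
        pos += increment_mm * _ramp((t - t0) / travel_time_s)
    return TableProfile(t, pos, float(increment_mm), float(travel_time_s), step_start_times)
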