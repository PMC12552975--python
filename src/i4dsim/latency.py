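"""System-latency estimation from sudden-stop sinusoid runs.

The measurement protocol drives the phantom with a regular sinusoid and
inserts brief manual motion interruptions (sudden stops followed by
restarts). The abrupt transitions isolate unambiguous reference maxima: in
every run, the first local maximum after each stop is located in the test
and the reference trace, its time is refined by a least-squares sinusoid
fit over one cycle, and the relative latency is the difference of the two
refined peak times, averaged over stops, then aggregated (mean +/- SD) over
runs. Adding the reference tracker's own baseline delay (16.6 ms for the
optical reference used here) converts the relative to an absolute latency.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

from .prep import SignalTrace

logger = logging.getLogger(__name__)

#: baseline delay of the optical reference tracker, ms
REFERENCE_BASELINE_MS = 16.6


@dataclass(frozen=True)
class LatencyEstimate:
    relative_mean_ms: float
    relative_sd_ms: float
    n_runs: int
    per_run_ms: tuple[float, ...] = ()
    baseline_ms: float | None = None
    absolute_ms: float | None = None

    @property
    def absolute_ms_rounded(self) -> int | None:
        """Absolute latency rounded to the nearest ms (half away from zero)."""
        if self.absolute_ms is None:
            return None
        return int(math.floor(self.absolute_ms + 0.5))


def _sinusoid_peak_time(
    t: np.ndarray, y: np.ndarray, t_coarse: float, t_cycle_s: float
) -> float:
    """Refine a maximum's time by a least-squares sinusoid fit.

    Fits y = a sin(w t) + b cos(w t) + c (free amplitude/phase/offset,
    w = 2 pi / T) over one cycle centered on the coarse maximum and returns
    the fitted peak time nearest to it.
    """
    w = 2 * np.pi / t_cycle_s
    mask = np.abs(t - t_coarse) <= t_cycle_s / 2
    tt, yy = t[mask], y[mask]
    if len(tt) < 4:
        raise ValueError("too few samples around maximum for sinusoid fit")
    A = np.column_stack([np.sin(w * tt), np.cos(w * tt), np.ones_like(tt)])
    (a, b, _c), *_ = np.linalg.lstsq(A, yy, rcond=None)
    phi = math.atan2(b, a)  # y = R sin(w t + phi) + c
    t0 = (np.pi / 2 - phi) / w
    k = round((t_coarse - t0) / t_cycle_s)
    return float(t0 + k * t_cycle_s)


def _first_max_after(
    trace: SignalTrace, t_after: float, prominence_frac: float = 0.2
) -> float | None:
    y = trace.amplitudes
    span = float(np.ptp(y))
    if span <= 0:
        return None
    peaks, _ = find_peaks(y, prominence=prominence_frac * span)
    times = trace.timestamps[peaks]
    later = times[times > t_after + 1e-9]
    return float(later[0]) if len(later) else None


def _estimate_t_cycle(trace: SignalTrace) -> float:
    y = trace.amplitudes
    peaks, _ = find_peaks(y, prominence=0.2 * float(np.ptp(y)))
    times = trace.timestamps[peaks]
    if len(times) < 2:
        raise ValueError("cannot estimate cycle duration: fewer than 2 maxima")
    return float(np.median(np.diff(times)))


def estimate_latency(
    test,
    reference,
    stop_markers,
    t_cycle_s: float | None = None,
) -> LatencyEstimate:
    """Relative latency of ``test`` vs ``reference`` from sudden-stop runs.

    Parameters
    ----------
    test, reference : SignalTrace or list of SignalTrace
        One smoothed (not temporally aligned) trace pair per run.
    stop_markers : sequence of float, or one sequence per run
        Stop times (s); the first maximum after each stop is matched.
    t_cycle_s : float, optional
        Sinusoid cycle duration; estimated from the reference maxima spacing
        if omitted.
    """
    tests = [test] if isinstance(test, SignalTrace) else list(test)
    refs = [reference] if isinstance(reference, SignalTrace) else list(reference)
    if len(tests) != len(refs):
        raise ValueError("need one reference trace per test trace")
    markers = list(stop_markers)
    per_run_markers = (
        markers if markers and isinstance(markers[0], (list, tuple, np.ndarray))
        else [markers] * len(tests)
    )

    per_run: list[float] = []
    for run, (tr, rf, stops) in enumerate(zip(tests, refs, per_run_markers)):
        T = t_cycle_s if t_cycle_s is not None else _estimate_t_cycle(rf)
        diffs = []
        for s in stops:
            tm = _first_max_after(tr, s)
            rm = _first_max_after(rf, s)
            if tm is None or rm is None:
                logger.warning("run %d: no post-stop maximum found after t=%s", run, s)
                continue
            tm_ref = _sinusoid_peak_time(tr.timestamps, tr.amplitudes, tm, T)
            rm_ref = _sinusoid_peak_time(rf.timestamps, rf.amplitudes, rm, T)
            diffs.append(tm_ref - rm_ref)
        if diffs:
            per_run.append(float(np.mean(diffs)))
        else:
            logger.warning("run %d skipped: no usable post-stop maxima", run)
    if not per_run:
        raise ValueError("all runs skipped: no post-stop maxima found")

    arr = 1000.0 * np.asarray(per_run)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return LatencyEstimate(float(arr.mean()), sd, len(arr), tuple(arr))


def to_absolute(
    rel: LatencyEstimate, baseline_ms: float = REFERENCE_BASELINE_MS
) -> LatencyEstimate:
    """Convert a relative latency to absolute by adding the reference
    tracker's baseline delay (treated as a deterministic constant)."""
    return replace(
        rel, baseline_ms=baseline_ms, absolute_ms=rel.relative_mean_ms + baseline_ms
    )
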