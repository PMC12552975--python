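"""Signal-agreement metrics.

For measured amplitudes x_i and reference amplitudes y_i on a common grid:

    BR   = 60 / T_cycle                          [breaths / min]
    RMSE = sqrt( (1/N) sum (x_i - y_i)^2 )       [mm]
    MAE  = (1/N) sum |x_i - y_i|                 [mm]
    r    = Pearson correlation coefficient

Phase-specific RMSE and r are computed per breathing cycle over the inhale
and exhale samples separately (cycles detected on the reference signal) and
averaged, unweighted, across all complete cycles of a session.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .prep import CycleSegmentation, SignalTrace

logger = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    """Global and phase-specific agreement metrics (partial fields allowed)."""

    n_samples: int = 0
    rmse_mm: float | None = None
    mae_mm: float | None = None
    r: float | None = None
    br_bpm: float | None = None
    rmse_inh_mm: float | None = None
    rmse_exh_mm: float | None = None
    r_inh: float | None = None
    r_exh: float | None = None
    n_cycles: int | None = None

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "br_bpm": self.br_bpm,
            "rmse_mm": self.rmse_mm,
            "mae_mm": self.mae_mm,
            "r": self.r,
            "rmse_inh_mm": self.rmse_inh_mm,
            "rmse_exh_mm": self.rmse_exh_mm,
            "r_inh": self.r_inh,
            "r_exh": self.r_exh,
            "n_cycles": self.n_cycles,
        }


def _amplitudes(x) -> np.ndarray:
    if isinstance(x, SignalTrace):
        return x.amplitudes
    return np.asarray(x, dtype=float)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; NaN (with a warning) if either input is constant."""
    dx = x - x.mean()
    dy = y - y.mean()
    denom = math.sqrt(float(np.sum(dx * dx)) * float(np.sum(dy * dy)))
    if denom == 0.0:
        logger.warning("Pearson r undefined for a constant trace; reporting NaN")
        return math.nan
    return float(np.sum(dx * dy) / denom)


def global_metrics(x, y) -> MetricsReport:
    """RMSE, MAE and Pearson r between measured x and reference y."""
    xa, ya = _amplitudes(x), _amplitudes(y)
    if len(xa) != len(ya):
        raise ValueError(f"length mismatch: {len(xa)} vs {len(ya)}")
    if len(xa) < 2:
        raise ValueError("metrics require at least 2 samples")
    d = xa - ya
    return MetricsReport(
        n_samples=len(xa),
        rmse_mm=float(np.sqrt(np.mean(d * d))),
        mae_mm=float(np.mean(np.abs(d))),
        r=_pearson(xa, ya),
    )


def _phase_samples(t: np.ndarray, interval: tuple[float, float]) -> np.ndarray:
    lo, hi = interval
    return np.nonzero((t >= lo - 1e-12) & (t <= hi + 1e-12))[0]


def phase_metrics(
    x: SignalTrace, y: SignalTrace, seg: CycleSegmentation, min_samples: int = 3
) -> MetricsReport:
    """Per-cycle inhale/exhale RMSE and r, averaged across complete cycles.

    ``seg`` must come from the reference signal ``y``. Phases with fewer than
    ``min_samples`` samples are skipped; constant segments contribute no r.
    """
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    t = y.timestamps
    xa, ya = x.amplitudes, y.amplitudes
    rmse_inh, rmse_exh, r_inh, r_exh = [], [], [], []
    n_used = 0
    for t0, tm, t1 in seg.cycles:
        used = False
        for interval, rmses, rs in (
            ((t0, tm), rmse_inh, r_inh),
            ((tm, t1), rmse_exh, r_exh),
        ):
            idx = _phase_samples(t, interval)
            if len(idx) < min_samples:
                logger.warning(
                    "phase %s has %d samples (< %d); skipped", interval, len(idx), min_samples
                )
                continue
            d = xa[idx] - ya[idx]
            rmses.append(float(np.sqrt(np.mean(d * d))))
            rv = _pearson(xa[idx], ya[idx])
            if not math.isnan(rv):
                rs.append(rv)
            used = True
        if used:
            n_used += 1

    def _mean(vals):
        return float(np.mean(vals)) if vals else None

    return MetricsReport(
        n_samples=len(x),
        rmse_inh_mm=_mean(rmse_inh),
        rmse_exh_mm=_mean(rmse_exh),
        r_inh=_mean(r_inh),
        r_exh=_mean(r_exh),
        n_cycles=n_used,
    )


def combine(global_report: MetricsReport, phase_report: MetricsReport,
            br_bpm: float | None = None) -> MetricsReport:
    """Merge global and phase-specific partial reports into one."""
    return MetricsReport(
        n_samples=global_report.n_samples,
        rmse_mm=global_report.rmse_mm,
        mae_mm=global_report.mae_mm,
        r=global_report.r,
        br_bpm=br_bpm,
        rmse_inh_mm=phase_report.rmse_inh_mm,
        rmse_exh_mm=phase_report.rmse_exh_mm,
        r_inh=phase_report.r_inh,
        r_exh=phase_report.r_exh,
        n_cycles=phase_report.n_cycles,
    )


def aggregate(reports: list[MetricsReport]) -> dict[str, tuple[float, float]]:
    """Unweighted mean +/- SD of each metric across repeated sessions."""
    out: dict[str, tuple[float, float]] = {}
    keys = ["br_bpm", "rmse_mm", "mae_mm", "r", "rmse_inh_mm", "rmse_exh_mm", "r_inh", "r_exh"]
    for key in keys:
        vals = [getattr(rep, key) for rep in reports]
        vals = [v for v in vals if v is not None and not math.isnan(v)]
        if vals:
            arr = np.asarray(vals, dtype=float)
            sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
            out[key] = (float(arr.mean()), sd)
    return out
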