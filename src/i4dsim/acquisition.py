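"""Prospective breathing-gated sequential acquisition and 20-bin virtual
reconstruction.

The acquisition simulator is a documented simplification of a prospective
breathing-synchronized sequential 4DCT controller: at each couch position
the beam switches on at the first detected cycle-start minimum of the
real-time surrogate, stays on until one full breathing cycle plus one
gantry rotation has been observed (the data-completeness rule), then the
couch travels to the next position.

Reconstruction is virtualized: instead of forming CT images, each beam-on
sample is assigned to one of 20 phase (PB) or amplitude (AB) bins from the
surrogate, and the per-bin tumor center-of-mass (COM) is the mean of the
*true* tumor position over that bin's acquisition timestamps. Latency
between the surrogate (used for binning) and the tumor (ground truth) then
manifests directly as a COM lag, which is the measurand of interest.

Bin conventions
---------------
AB: 10 exhale bins Exh100..Exh10 (descending normalized amplitude decile)
followed by 10 inhale bins Inh10..Inh100 (ascending); Inh0 denotes the
end-exhale minimum between Exh10 and Inh10. PB: 20 uniform phase bins per
cycle starting at the cycle-start minimum (inhale first), labelled by the
amplitude decile the ideal waveform traverses.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .prep import CycleSegmentation, SignalTrace, detect_cycles
from .waveforms import (
    NOMINAL_TABLE_INCREMENT_MM,
    TumorMotionSpec,
    TumorTrajectory,
    WaveformSpec,
)

logger = logging.getLogger(__name__)

N_BINS = 20

AB_LABELS = [f"Exh{p}" for p in range(100, 0, -10)] + [f"Inh{p}" for p in range(10, 101, 10)]
AB_IS_EXHALE = np.array([True] * 10 + [False] * 10)
PB_LABELS = [f"Inh{p}" for p in range(10, 101, 10)] + [f"Exh{p}" for p in range(100, 0, -10)]
PB_IS_EXHALE = np.array([False] * 10 + [True] * 10)


def nominal_table_increment(
    n_rows: int = 64, row_width_mm: float = 0.6, increment_factor: float = 0.9
) -> float:
    """Couch increment of the sequential scan: factor x total collimation."""
    return increment_factor * n_rows * row_width_mm


class AcquisitionError(RuntimeError):
    """Raised when the gating rule cannot be satisfied before the trace ends."""


@dataclass(frozen=True)
class AcquisitionConfig:
    n_couch_positions: int = 4
    table_increment_mm: float = NOMINAL_TABLE_INCREMENT_MM
    rotation_time_s: float = 0.5
    travel_time_s: float = 0.8
    trigger: str = "cycle_start_min"
    start_time_s: float = 2.0

    def __post_init__(self) -> None:
        if self.n_couch_positions < 1:
            raise ValueError(f"n_couch_positions must be >= 1, got {self.n_couch_positions}")
        if not self.rotation_time_s > 0:
            raise ValueError(f"rotation_time_s must be > 0, got {self.rotation_time_s}")
        if not self.table_increment_mm > 0:
            raise ValueError(f"table_increment_mm must be > 0, got {self.table_increment_mm}")
        if self.trigger != "cycle_start_min":
            raise ValueError(f"unknown trigger rule {self.trigger!r}")


@dataclass
class BeamOnWindow:
    position_index: int
    start_s: float
    stop_s: float
    sample_times: np.ndarray
    sample_amplitudes: np.ndarray


@dataclass
class AcquisitionRecord:
    windows: list[BeamOnWindow]
    config: AcquisitionConfig
    step_start_times: np.ndarray

    @property
    def all_sample_times(self) -> np.ndarray:
        return np.concatenate([w.sample_times for w in self.windows])

    def mark_xray(self, trace: SignalTrace) -> SignalTrace:
        """Return a copy of ``trace`` with beam-on flags set from the record."""
        flags = np.zeros(len(trace), dtype=bool)
        for w in self.windows:
            flags |= (trace.timestamps >= w.start_s) & (trace.timestamps < w.stop_s)
        return trace.copy_with(xray_on=flags)


def simulate_acquisition(
    surrogate_rt: SignalTrace,
    cfg: AcquisitionConfig = AcquisitionConfig(),
    segmentation: CycleSegmentation | None = None,
) -> AcquisitionRecord:
    """Run the gated sequential acquisition on a real-time surrogate trace.

    ``surrogate_rt`` should be the latency-affected (optionally predicted and
    smoothed) signal the scanner would see. Beam-on at each couch position
    spans one observed breathing cycle plus one rotation time.
    """
    seg = segmentation or detect_cycles(surrogate_rt)
    minima = seg.minima_times
    t_end = surrogate_rt.timestamps[-1]
    cursor = cfg.start_time_s
    windows: list[BeamOnWindow] = []
    step_starts: list[float] = []
    for p in range(cfg.n_couch_positions):
        idx = int(np.searchsorted(minima, cursor))
        if idx + 1 >= len(minima):
            raise AcquisitionError(
                f"no trigger/cycle found for couch position {p} before trace end; "
                f"completed {p} of {cfg.n_couch_positions} positions"
            )
        t_on = float(minima[idx])
        t_next_min = float(minima[idx + 1])
        t_off = t_next_min + cfg.rotation_time_s
        if t_off > t_end:
            raise AcquisitionError(
                f"trace ends before beam-off at couch position {p}; "
                f"completed {p} of {cfg.n_couch_positions} positions"
            )
        mask = (surrogate_rt.timestamps >= t_on) & (surrogate_rt.timestamps < t_off)
        windows.append(
            BeamOnWindow(
                p,
                t_on,
                t_off,
                surrogate_rt.timestamps[mask].copy(),
                surrogate_rt.amplitudes[mask].copy(),
            )
        )
        if p < cfg.n_couch_positions - 1:
            step_starts.append(t_off)
        cursor = t_off + cfg.travel_time_s
    return AcquisitionRecord(windows, cfg, np.asarray(step_starts))


@dataclass
class BinAssignment:
    mode: str  # "PB" or "AB"
    labels: list[str]
    is_exhale: np.ndarray
    sample_times: np.ndarray
    sample_bins: np.ndarray
    n_outside: int = 0


def _cycle_index(seg: CycleSegmentation, t: float) -> tuple[int, bool]:
    """Index of the complete cycle containing t (nearest cycle if outside)."""
    starts = np.array([c[0] for c in seg.cycles])
    ends = np.array([c[2] for c in seg.cycles])
    i = int(np.searchsorted(starts, t, side="right")) - 1
    if i < 0:
        return 0, True
    if t > ends[i] + 1e-12:
        if i + 1 < len(seg.cycles):
            return i + 1, True  # gap between cycles: take the next one
        return i, True
    return i, False


def assign_bins(
    record: AcquisitionRecord,
    surrogate_rt: SignalTrace,
    mode: str,
    segmentation: CycleSegmentation | None = None,
) -> BinAssignment:
    """Assign every beam-on sample to one of 20 phase or amplitude bins.

    PB: the phase fraction (time since the cycle-start minimum over the
    cycle duration) maps uniformly onto 20 bins. AB: the cycle-normalized
    amplitude decile, split by breathing direction (exhale bins descending,
    inhale ascending). Samples outside any complete cycle are mapped via the
    nearest complete cycle and counted.
    """
    if mode not in ("PB", "AB"):
        raise ValueError(f"mode must be 'PB' or 'AB', got {mode!r}")
    seg = segmentation or detect_cycles(surrogate_rt)
    t_all = record.all_sample_times
    y_all = np.interp(t_all, surrogate_rt.timestamps, surrogate_rt.amplitudes)

    # per-cycle amplitude extremes for AB normalization
    cyc_min, cyc_max = [], []
    ts, ys = surrogate_rt.timestamps, surrogate_rt.amplitudes
    for t0, _tm, t1 in seg.cycles:
        m = (ts >= t0) & (ts <= t1)
        cyc_min.append(float(ys[m].min()))
        cyc_max.append(float(ys[m].max()))

    bins = np.empty(len(t_all), dtype=int)
    n_outside = 0
    for i, (t, y) in enumerate(zip(t_all, y_all)):
        ci, outside = _cycle_index(seg, t)
        n_outside += outside
        t0, tm, t1 = seg.cycles[ci]
        if mode == "PB":
            phase = np.clip((t - t0) / (t1 - t0), 0.0, 1.0 - 1e-12)
            bins[i] = int(phase * N_BINS)
        else:
            span = cyc_max[ci] - cyc_min[ci]
            a = np.clip((y - cyc_min[ci]) / span, 0.0, 1.0) if span > 0 else 0.0
            d = min(max(int(np.ceil(a * 10)), 1), 10)  # amplitude decile 1..10
            exhaling = t > tm
            bins[i] = (10 - d) if exhaling else (9 + d)
    if n_outside:
        logger.warning("%d beam-on samples outside complete cycles; mapped to nearest", n_outside)
    labels = PB_LABELS if mode == "PB" else AB_LABELS
    is_exh = PB_IS_EXHALE if mode == "PB" else AB_IS_EXHALE
    return BinAssignment(mode, list(labels), is_exh.copy(), t_all, bins, n_outside)


@dataclass
class BinnedReconstruction:
    """20 bins x 3-axis tumor COM positions with per-bin sample counts."""

    mode: str
    labels: list[str]
    is_exhale: np.ndarray
    com_mm: np.ndarray  # (20, 3), NaN where a bin is empty
    counts: np.ndarray  # (20,)


def reconstruct_com(
    assignment: BinAssignment, tumor: TumorTrajectory
) -> BinnedReconstruction:
    """Per-bin tumor COM: mean true tumor position over the bin's samples."""
    pos = tumor.positions_at(assignment.sample_times)  # (n, 3)
    com = np.full((N_BINS, 3), np.nan)
    counts = np.zeros(N_BINS, dtype=int)
    for b in range(N_BINS):
        m = assignment.sample_bins == b
        counts[b] = int(m.sum())
        if counts[b]:
            com[b] = pos[m].mean(axis=0)
    empty = np.nonzero(counts == 0)[0]
    if len(empty):
        logger.warning("empty bins flagged missing: %s",
                       [assignment.labels[b] for b in empty])
    return BinnedReconstruction(
        assignment.mode, list(assignment.labels), assignment.is_exhale.copy(), com, counts
    )


def reference_trajectory(
    mode: str, spec: WaveformSpec | None, tumor: TumorMotionSpec
) -> BinnedReconstruction:
    """Ideal per-bin reference positions for regular breathing.

    AB: amplitude linear in bin index from full inhale down to full exhale
    across the 10 exhale bins and back up across the 10 inhale bins
    (peak-to-peak exactly the axis amplitude). PB: the ideal cos^6 shape
    evaluated at the 20 bin-center phases (cycle starting at end-exhale).
    """
    if mode == "AB":
        frac = np.concatenate([np.linspace(1.0, 0.0, 10), np.linspace(0.0, 1.0, 10)])
        labels, is_exh = AB_LABELS, AB_IS_EXHALE
    elif mode == "PB":
        if spec is None or spec.family != "cos6":
            raise ValueError("PB reference requires a regular cos6 waveform spec")
        centers = (np.arange(N_BINS) + 0.5) / N_BINS
        # cos^6 cycle re-phased to start at the end-exhale minimum
        frac = np.sin(np.pi * centers) ** 6
        labels, is_exh = PB_LABELS, PB_IS_EXHALE
    else:
        raise ValueError(f"mode must be 'PB' or 'AB', got {mode!r}")
    ref = frac[:, None] * tumor.amplitudes[None, :]
    return BinnedReconstruction(mode, list(labels), is_exh.copy(), ref,
                                np.zeros(N_BINS, dtype=int))


@dataclass
class ComDeviationReport:
    """Per-bin and grouped COM deviations (measured - reference), mm.

    Exhale-bin deviations are sign-inverted so that positive values indicate
    a lag of the reconstructed COM behind the reference. Per-bin statistics
    are mean +/- SD over the repeated scans; group values average the
    per-bin means over the exhale and inhale bin groups (axis order
    S-I, A-P, L-M).
    """

    mode: str
    labels: list[str]
    is_exhale: np.ndarray
    n_repeats: int
    per_bin_mean: np.ndarray  # (20, 3)
    per_bin_sd: np.ndarray  # (20, 3)
    exh_group_mean: np.ndarray  # (3,) signed
    inh_group_mean: np.ndarray  # (3,) signed
    exh_group_abs_mean: np.ndarray  # (3,) mean of |per-bin mean|
    inh_group_abs_mean: np.ndarray  # (3,)
    per_repeat_exh_group: np.ndarray  # (n_repeats, 3) signed


def com_deviation(
    recons: BinnedReconstruction | list[BinnedReconstruction],
    reference: BinnedReconstruction,
) -> ComDeviationReport:
    """Deviation of reconstructed COM from the per-bin reference."""
    rec_list = [recons] if isinstance(recons, BinnedReconstruction) else list(recons)
    if not rec_list:
        raise ValueError("need at least one reconstruction")
    for rec in rec_list:
        if rec.mode != reference.mode or rec.com_mm.shape != reference.com_mm.shape:
            raise ValueError("reconstruction and reference bin structures differ")
    is_exh = reference.is_exhale
    sign = np.where(is_exh, -1.0, 1.0)[:, None]
    devs = np.stack([(rec.com_mm - reference.com_mm) * sign for rec in rec_list])
    if np.isnan(devs).any():
        logger.warning("missing bins excluded from group means")
    with np.errstate(invalid="ignore"):
        per_bin_mean = np.nanmean(devs, axis=0)
        per_bin_sd = (
            np.nanstd(devs, axis=0, ddof=1) if len(rec_list) > 1 else np.zeros_like(per_bin_mean)
        )
        exh_mean = np.nanmean(per_bin_mean[is_exh], axis=0)
        inh_mean = np.nanmean(per_bin_mean[~is_exh], axis=0)
        exh_abs = np.nanmean(np.abs(per_bin_mean[is_exh]), axis=0)
        inh_abs = np.nanmean(np.abs(per_bin_mean[~is_exh]), axis=0)
        per_rep_exh = np.nanmean(devs[:, is_exh, :], axis=1)
    return ComDeviationReport(
        reference.mode,
        list(reference.labels),
        is_exh.copy(),
        len(rec_list),
        per_bin_mean,
        per_bin_sd,
        exh_mean,
        inh_mean,
        exh_abs,
        inh_abs,
        per_rep_exh,
    )
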