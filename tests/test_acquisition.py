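"""Gated acquisition simulation, 20-bin assignment, virtual COM
reconstruction and deviation analysis."""
import numpy as np
import pytest

from i4dsim import (
    AcquisitionConfig,
    AcquisitionError,
    PredictorSpec,
    SurrogateSpec,
    TumorMotionSpec,
    WaveformSpec,
    apply_surrogate,
    assign_bins,
    com_deviation,
    detect_cycles,
    from_waveform,
    generate_tumor_trajectory,
    generate_waveform,
    nominal_table_increment,
    reconstruct_com,
    reference_trajectory,
    simulate_acquisition,
    smooth,
)
from i4dsim.acquisition import AB_LABELS, BinAssignment, BinnedReconstruction, N_BINS
from i4dsim.experiment import run_scenario


@pytest.fixture
def regular_acquisition(cos6_trace):
    cfg = AcquisitionConfig(n_couch_positions=4, rotation_time_s=0.5)
    seg = detect_cycles(cos6_trace)
    record = simulate_acquisition(cos6_trace, cfg, segmentation=seg)
    return record, seg, cfg


class TestSimulateAcquisition:
    def test_beam_on_covers_cycle_plus_rotation(self, regular_acquisition):
        record, _, _ = regular_acquisition
        for w in record.windows:
            assert (w.stop_s - w.start_s) == pytest.approx(3.0 + 0.5, abs=0.05)

    def test_disjoint_ordered_intervals(self, regular_acquisition):
        record, _, _ = regular_acquisition
        assert len(record.windows) == 4
        for a, b in zip(record.windows, record.windows[1:]):
            assert a.stop_s <= b.start_s

    def test_trigger_at_cycle_start_minimum(self, regular_acquisition, cos6_trace):
        record, seg, _ = regular_acquisition
        for w in record.windows:
            assert np.min(np.abs(seg.minima_times - w.start_s)) < 1e-9

    def test_irregular_cycle_extends_beam_on(self):
        spec = WaveformSpec("irregular", 15.0, 4.0, duration_s=120.0,
                            a_range_mm=(10.0, 20.0), t_range_s=(2.5, 6.0), seed=3)
        trace = from_waveform(generate_waveform(spec))
        seg = detect_cycles(trace)
        record = simulate_acquisition(trace, AcquisitionConfig(4), segmentation=seg)
        durations = [w.stop_s - w.start_s - 0.5 for w in record.windows]
        # each beam-on spans exactly the triggered breathing cycle
        minima = seg.minima_times
        for w, dur in zip(record.windows, durations):
            i = int(np.argmin(np.abs(minima - w.start_s)))
            assert dur == pytest.approx(minima[i + 1] - minima[i], abs=1e-6)
        assert np.ptp(durations) > 0.3  # cycles genuinely vary

    def test_insufficient_trace_errors_with_position_count(self, cos6_trace):
        with pytest.raises(AcquisitionError, match="completed"):
            simulate_acquisition(cos6_trace, AcquisitionConfig(n_couch_positions=40))


class TestAssignBins:
    def test_pb_bin_zero_at_cycle_start_minimum(self, regular_acquisition, cos6_trace):
        record, seg, _ = regular_acquisition
        assignment = assign_bins(record, cos6_trace, "PB", segmentation=seg)
        starts = np.array([c[0] for c in seg.cycles])
        for w in record.windows:
            i = int(np.argmin(np.abs(assignment.sample_times - w.start_s)))
            t = assignment.sample_times[i]
            if np.min(np.abs(starts - t)) < 1e-9:
                assert assignment.sample_bins[i] == 0

    def test_ab_full_amplitude_inhaling_maps_to_top_inhale_bin(
        self, regular_acquisition, cos6_trace
    ):
        record, seg, _ = regular_acquisition
        assignment = assign_bins(record, cos6_trace, "AB", segmentation=seg)
        y = np.interp(assignment.sample_times, cos6_trace.timestamps, cos6_trace.amplitudes)
        near_peak = y > 0.99 * cos6_trace.amplitudes.max()
        top_bins = {AB_LABELS.index("Inh100"), AB_LABELS.index("Exh100")}
        assert set(assignment.sample_bins[near_peak]) <= top_bins
        assert AB_LABELS.index("Inh100") in set(assignment.sample_bins[near_peak])

    def test_pb_counts_near_uniform_over_a_complete_cycle(self, regular_acquisition,
                                                          cos6_trace):
        record, seg, _ = regular_acquisition
        assignment = assign_bins(record, cos6_trace, "PB", segmentation=seg)
        # restrict to the first window's complete triggered cycle
        w = record.windows[0]
        cycle_end = w.stop_s - 0.5
        m = (assignment.sample_times >= w.start_s) & (assignment.sample_times < cycle_end)
        counts = np.bincount(assignment.sample_bins[m], minlength=N_BINS)
        assert counts.max() - counts.min() <= 2

    def test_every_beam_on_sample_assigned(self, regular_acquisition, cos6_trace):
        record, seg, _ = regular_acquisition
        for mode in ("PB", "AB"):
            assignment = assign_bins(record, cos6_trace, mode, segmentation=seg)
            assert len(assignment.sample_bins) == len(record.all_sample_times)
            assert np.all((assignment.sample_bins >= 0) & (assignment.sample_bins < N_BINS))


class TestReferenceTrajectory:
    def test_ab_triangle_peak_to_peak_equals_axis_amplitude(self):
        ref = reference_trajectory("AB", None, TumorMotionSpec(15.0, 2.0, 2.0))
        si = ref.com_mm[:, 0]
        assert si.max() - si.min() == pytest.approx(15.0, abs=1e-12)
        # piecewise linear: full inhale -> full exhale -> full inhale
        assert si[0] == pytest.approx(15.0) and si[-1] == pytest.approx(15.0)
        assert np.all(np.diff(si[:10]) < 0) and np.all(np.diff(si[10:]) > 0)

    def test_pb_reference_symmetric_about_mid_cycle(self, cos6_spec):
        ref = reference_trajectory("PB", cos6_spec, TumorMotionSpec(15.0, 2.0, 2.0))
        si = ref.com_mm[:, 0]
        assert np.allclose(si, si[::-1], atol=1e-12)
        # the two mid-cycle bin centers sit at phase 0.475 / 0.525 of the cycle
        assert si.max() == pytest.approx(15.0 * np.sin(np.pi * 0.475) ** 6, abs=1e-9)

    def test_pb_requires_regular_waveform(self):
        with pytest.raises(ValueError, match="cos6"):
            reference_trajectory("PB", None, TumorMotionSpec(15.0, 2.0, 2.0))


class TestReconstructCom:
    def test_zero_latency_pb_matches_ideal_within_discretization(
        self, cos6_spec, regular_acquisition, cos6_wave, cos6_trace
    ):
        record, seg, _ = regular_acquisition
        tumor = generate_tumor_trajectory(cos6_wave, TumorMotionSpec(15.0, 2.0, 2.0))
        assignment = assign_bins(record, cos6_trace, "PB", segmentation=seg)
        recon = reconstruct_com(assignment, tumor)
        ref = reference_trajectory("PB", cos6_spec, tumor.spec)
        dev = np.abs(recon.com_mm[:, 0] - ref.com_mm[:, 0])
        # bound: amplitude x max phase slope of cos^6 x half bin width
        bound = 15.0 * 4.9 * 0.5 / N_BINS
        assert np.nanmax(dev) <= bound

    def test_zero_amplitude_axis_constant(self, regular_acquisition, cos6_wave, cos6_trace):
        record, seg, _ = regular_acquisition
        tumor = generate_tumor_trajectory(cos6_wave, TumorMotionSpec(15.0, 0.0, 0.0))
        assignment = assign_bins(record, cos6_trace, "AB", segmentation=seg)
        recon = reconstruct_com(assignment, tumor)
        assert np.allclose(recon.com_mm[~np.isnan(recon.com_mm[:, 1]), 1], 0.0, atol=1e-12)

    def test_empty_bin_flagged_missing(self, cos6_wave):
        tumor = generate_tumor_trajectory(cos6_wave, TumorMotionSpec(15.0, 2.0, 2.0))
        assignment = BinAssignment(
            "AB", list(AB_LABELS), np.array([True] * 10 + [False] * 10),
            sample_times=np.array([1.0, 1.1]), sample_bins=np.array([0, 5]),
        )
        recon = reconstruct_com(assignment, tumor)
        assert np.isnan(recon.com_mm[7, 0])
        assert recon.counts[7] == 0


class TestComDeviation:
    def _identical_recon(self, ref):
        return BinnedReconstruction(ref.mode, list(ref.labels), ref.is_exhale.copy(),
                                    ref.com_mm.copy(), np.ones(N_BINS, dtype=int))

    def test_recon_equals_reference_gives_zero(self):
        ref = reference_trajectory("AB", None, TumorMotionSpec(15.0, 2.0, 2.0))
        rep = com_deviation(self._identical_recon(ref), ref)
        assert np.allclose(rep.per_bin_mean, 0.0, atol=1e-12)
        assert np.allclose(rep.exh_group_mean, 0.0, atol=1e-12)

    def test_exhale_sign_inversion_makes_lag_positive(self):
        ref = reference_trajectory("AB", None, TumorMotionSpec(15.0, 2.0, 2.0))
        rec = self._identical_recon(ref)
        rec.com_mm = rec.com_mm.copy()
        rec.com_mm[ref.is_exhale, 0] -= 0.3  # measured below reference during exhale
        rep = com_deviation(rec, ref)
        assert rep.exh_group_mean[0] == pytest.approx(0.3, abs=1e-12)
        assert rep.inh_group_mean[0] == pytest.approx(0.0, abs=1e-12)

    def test_identical_repeats_have_zero_sd(self):
        ref = reference_trajectory("AB", None, TumorMotionSpec(15.0, 2.0, 2.0))
        reps = [self._identical_recon(ref) for _ in range(3)]
        rep = com_deviation(reps, ref)
        assert rep.n_repeats == 3
        assert np.allclose(rep.per_bin_sd, 0.0, atol=1e-12)


class TestChainProperties:
    def test_exhale_ab_deviation_monotone_in_latency(self):
        """Exhale-group AB deviation grows with injected surrogate latency
        (regular 20 BPM / 15 mm scenario, noiseless)."""
        values = []
        for latency in (0.0, 0.03, 0.063, 0.1):
            res = run_scenario(
                WaveformSpec("cos6", 15.0, 3.0, 120.0), TumorMotionSpec(15.0, 2.0, 2.0),
                SurrogateSpec(latency_s=latency), None, AcquisitionConfig(4),
                n_repeats=1, seed=0, modes=("AB",),
            )
            values.append(res.com_reports["AB"].exh_group_mean[0])
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_fine_grid_chain_consistency(self):
        """The whole chain at 2 ms sampling agrees with the 20 ms grid to
        within 0.1 mm on the group means."""
        groups = {}
        for dt in (0.02, 0.002):
            res = run_scenario(
                WaveformSpec("cos6", 15.0, 3.0, 60.0, dt_s=dt),
                TumorMotionSpec(15.0, 2.0, 2.0),
                SurrogateSpec(latency_s=0.063), None,
                AcquisitionConfig(n_couch_positions=3), n_repeats=1, seed=0,
            )
            groups[dt] = {m: res.com_reports[m].exh_group_mean[0] for m in ("PB", "AB")}
        for mode in ("PB", "AB"):
            assert groups[0.02][mode] == pytest.approx(groups[0.002][mode], abs=0.1)


def test_nominal_table_increment_from_geometry():
    assert nominal_table_increment() == pytest.approx(34.56, abs=1e-12)
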