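"""Spike detection, artifact rejection, sorting, metrics and the outlier pass."""

import numpy as np
import pytest

from imequant.ephys import (
    RecordingBlock,
    SpikeEvent,
    channel_metrics,
    cluster_units,
    common_median_reference,
    detect_spikes,
    estimate_sigma,
    extract_waveforms,
    noise_rms,
    reject_coincident,
    reject_overrange,
    rout_filter,
    spike_rate,
    validate_units,
)
from imequant.synth.recording import spike_template

FS = 24414.0


def ev(channel, t_index, peak=-100.0):
    return SpikeEvent(channel=channel, t_index=t_index, peak_amp=peak)


class TestReferencing:
    def test_zero_and_common_mode_inputs_cancel(self):
        zeros = RecordingBlock(np.zeros((4, 100)), FS)
        assert np.all(common_median_reference(zeros).samples == 0)
        common = RecordingBlock(np.tile(np.sin(np.arange(100)), (4, 1)), FS)
        assert np.allclose(common_median_reference(common).samples, 0, atol=1e-6)

    def test_median_subtracted_per_sample(self):
        col = np.arange(1, 17, dtype=float).reshape(16, 1)
        out = common_median_reference(RecordingBlock(col, FS))
        assert out.samples[0, 0] == pytest.approx(-7.5)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            common_median_reference(RecordingBlock(np.zeros((1, 10)), FS))


class TestSigmaEstimation:
    def test_known_values(self):
        assert estimate_sigma(np.zeros(100)) == 0.0
        assert estimate_sigma(np.tile([-1.0, 0.0, 1.0], 100)) == pytest.approx(1 / 0.6745)

    def test_consistent_for_gaussian_noise(self, rng):
        x = rng.standard_normal(1_000_000)
        assert estimate_sigma(x) == pytest.approx(1.0, abs=0.01)


class TestDetection:
    def test_flat_trace_yields_nothing(self):
        assert detect_spikes(np.zeros(100), sigma=1.0, fs=FS) == []

    def test_single_crossing_at_local_minimum(self):
        trace = np.array([0.0, 0.0, -5.0, 0.0, 0.0])
        events = detect_spikes(trace, sigma=1.0, fs=FS)
        assert len(events) == 1
        assert events[0].t_index == 2
        assert events[0].peak_amp == -5.0

    def test_threshold_is_strictly_four_sigma(self):
        trace = np.array([0.0, 0.0, -3.9, 0.0, 0.0])
        assert detect_spikes(trace, sigma=1.0, fs=FS) == []

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes(np.zeros(10), sigma=0.0, fs=FS)

    def test_lockout_merges_adjacent_minima(self):
        trace = np.zeros(100)
        trace[10] = -5.0
        trace[15] = -6.0  # within 1 ms of the first at 24.414 kHz
        events = detect_spikes(trace, sigma=1.0, fs=FS)
        assert len(events) == 1


class TestArtifactFilters:
    def test_overrange_boundary_is_strict(self):
        events = [ev(0, 10, -520.0), ev(0, 20, -499.0), ev(0, 30, -500.0)]
        kept = reject_overrange(events)
        assert [e.peak_amp for e in kept] == [-499.0, -500.0]
        assert reject_overrange([]) == []

    def test_coincidence_requires_more_than_14_distinct_channels(self):
        fifteen = [ev(c, 100) for c in range(15)]
        assert reject_coincident(fifteen, FS) == []
        fourteen = [ev(c, 100) for c in range(14)]
        assert len(reject_coincident(fourteen, FS)) == 14

    def test_same_channel_repeats_are_not_coincident(self):
        burst = [ev(3, 100 + i) for i in range(15)]
        assert len(reject_coincident(burst, FS)) == 15

    def test_filters_commute(self):
        events = (
            [ev(c, 100) for c in range(16)]  # coincident group
            + [ev(0, 500, -600.0), ev(1, 900, -120.0)]
        )
        a = reject_coincident(reject_overrange(events), FS)
        b = reject_overrange(reject_coincident(events, FS))
        assert a == b


class TestWaveforms:
    def test_edge_events_dropped_and_interior_kept(self):
        trace = np.zeros(1000)
        trace[500] = -100.0
        events = [ev(0, 0), ev(0, 500)]
        snippets, kept = extract_waveforms(trace, events, FS)
        assert len(kept) == 1
        assert kept[0].t_index == 500
        # trough sits at the pre-window mark
        assert np.argmin(snippets[0]) == int(round(0.6e-3 * FS))

    def test_count_conservation_for_interior_events(self):
        trace = np.random.default_rng(0).normal(size=5000)
        events = [ev(0, i) for i in range(100, 4800, 200)]
        snippets, kept = extract_waveforms(trace, events, FS)
        assert len(snippets) == len(events) == len(kept)


class TestClustering:
    def test_single_template_forms_one_unit(self, rng):
        template = spike_template(FS, 150.0)
        snippets = template + rng.normal(0, 3.0, size=(50, len(template)))
        events = [ev(0, 100 + 80 * i) for i in range(50)]
        units = cluster_units(snippets, events, channel=0)
        assert len(units) == 1
        assert units[0].vpp == pytest.approx(np.ptp(template), rel=0.05)

    def test_two_separated_templates_form_two_units(self, rng):
        t1 = spike_template(FS, 200.0 / 1.4, shape_id=0)
        t2 = spike_template(FS, 80.0 / 1.4, shape_id=1)
        snippets = np.vstack(
            [t1 + rng.normal(0, 2.0, size=(50, len(t1))),
             t2 + rng.normal(0, 2.0, size=(50, len(t2)))]
        )
        events = [ev(0, 100 + 80 * i) for i in range(100)]
        units = cluster_units(snippets, events, channel=0)
        assert len(units) == 2

    def test_few_snippets_force_single_unit(self, rng):
        snippets = rng.normal(size=(3, 59))
        units = cluster_units(snippets, [ev(0, i * 100 + 50) for i in range(3)], channel=0)
        assert len(units) == 1


class TestValidation:
    def test_vpp_floor_is_strict_less_than_40(self):
        def unit_with(minv, maxv):
            from imequant.ephys import SortedUnit

            wf = np.zeros(59)
            wf[20], wf[30] = minv, maxv
            return SortedUnit(0, np.array([100]), wf, 0)

        kept = validate_units([unit_with(-30, 15), unit_with(-30, 9), unit_with(-25, 15)])
        vpps = sorted(round(u.vpp) for u in kept)
        assert vpps == [40, 45]  # 39 removed, exactly 40 kept


class TestNoiseAndRate:
    def test_rms_of_known_signals(self):
        assert noise_rms(np.zeros(100), np.array([]), FS) == 0.0
        square = np.tile([3.0, -3.0], 500)
        assert noise_rms(square, np.array([]), FS) == pytest.approx(3.0)

    def test_excision_removes_spike_contribution(self, rng):
        trace = rng.normal(0, 1.0, 24414)
        trace[12000] = -500.0
        with_spike = noise_rms(trace, np.array([]), FS)
        excised = noise_rms(trace, np.array([12000]), FS)
        assert excised == pytest.approx(1.0, abs=0.05)
        assert with_spike > excised

    def test_full_excision_rejected(self):
        with pytest.raises(ValueError):
            noise_rms(np.zeros(10), np.array([5]), FS, excision_ms=1000.0)

    def test_rate_is_inverse_median_isi(self):
        idx = (np.array([0.0, 10.0, 30.0, 60.0]) * 1e-3 * FS).astype(int)
        assert spike_rate(idx, FS) == pytest.approx(50.0, rel=0.01)
        periodic = np.arange(0, 24414 * 2, int(FS / 10))
        assert spike_rate(periodic, FS) == pytest.approx(10.0, rel=0.01)
        assert np.isnan(spike_rate(np.array([5]), FS))


class TestRoutFilter:
    def test_identical_values_unflagged(self):
        kept, flagged = rout_filter(np.full(10, 5.0))
        assert flagged.sum() == 0

    def test_gross_outlier_flagged(self):
        kept, flagged = rout_filter(np.array([4.9, 5.0, 5.0, 5.1, 25.0]))
        assert flagged.tolist() == [False, False, False, False, True]

    def test_small_samples_pass_through(self):
        kept, flagged = rout_filter(np.array([1.0, 100.0]))
        assert flagged.sum() == 0

    def test_null_false_flag_rate_bounded_by_q(self, rng):
        rates = []
        for _ in range(20):
            x = rng.standard_normal(1000)
            _, flagged = rout_filter(x, q_percent=5.0)
            rates.append(flagged.mean())
        # under the null the FDR pass should flag well under Q = 5%
        assert np.mean(rates) <= 0.05 + 0.01


class TestChannelMetrics:
    def test_snr_is_vpp_over_noise(self, rng):
        from imequant.ephys import SortedUnit

        wf = np.zeros(59)
        wf[14], wf[30] = -110.0, 40.0  # Vpp 150
        unit = SortedUnit(0, np.array([5000, 7000, 9000]), wf, 0)
        trace = rng.normal(0, 25.0, 24414)
        m = channel_metrics([unit], trace, FS)
        assert m.vpp_mean == pytest.approx(150.0)
        assert m.snr == pytest.approx(150.0 / 25.0, rel=0.05)
        assert m.active

    def test_no_units_means_inactive(self):
        m = channel_metrics([], np.zeros(100), FS)
        assert not m.active
        assert m.n_units == 0


class TestEndToEnd:
    def test_detection_recall_and_precision_on_clean_units(self):
        """Templates at >= 8 sigma must be recovered with recall/precision >= 0.9."""
        from imequant import ephys
        from imequant.synth.recording import RecordingConfig, UnitSpec, gen_recording

        cfg = RecordingConfig(
            n_channels=16,
            duration=5.0,
            units=[UnitSpec(channel=c, rate_hz=10.0, amplitude_uv=120.0)
                   for c in range(16)],
            noise_sigma=7.5,
            motion_artifact_rate=0.0,
            overrange_artifact_rate=0.0,
            seed=21,
        )
        block, truth = gen_recording(cfg)
        _, units, _ = ephys.process_recording(block)
        spikes = truth.events[truth.events["kind"] == "spike"]
        tol = int(round(1e-3 * block.fs))
        truth_by_chan = {c: g["t_index"].to_numpy() for c, g in spikes.groupby("channel")}
        tp = fp = 0
        for u in units:
            tt = truth_by_chan.get(u.channel, np.array([np.iinfo(np.int64).max]))
            for s in u.spike_indices:
                if np.min(np.abs(tt - s)) <= tol:
                    tp += 1
                else:
                    fp += 1
        assert tp / len(spikes) >= 0.9  # recall through the validated output
        assert tp / (tp + fp) >= 0.9  # precision of the validated output

    def test_artifacts_never_survive_the_rejection_rules(self):
        """Detected events matching inserted artifacts are all filtered out."""
        from imequant import ephys
        from imequant.synth.recording import RecordingConfig, gen_recording

        cfg = RecordingConfig(
            n_channels=16, duration=5.0, units=[], noise_sigma=0.0,
            pink_fraction=0.0, motion_artifact_rate=2.0,
            overrange_artifact_rate=1.0, seed=9,
        )
        block, truth = gen_recording(cfg)
        assert (truth.events["kind"] != "spike").all() and len(truth.events) > 0
        events = []
        for ci in range(block.n_channels):
            # artifacts dominate; use a fixed sigma so detection sees them all
            events.extend(ephys.detect_spikes(block.samples[ci], 5.0, block.fs, channel=ci))
        assert events, "artifacts should be detected before filtering"
        survivors = ephys.reject_coincident(ephys.reject_overrange(events), block.fs)
        assert survivors == []

    def test_metrics_invariant_to_dc_offset_after_referencing(self, tiny_recording_config):
        from imequant import ephys
        from imequant.synth.recording import gen_recording

        block, _ = gen_recording(tiny_recording_config)
        metrics_a, _, _ = ephys.process_recording(block)
        shifted = ephys.RecordingBlock(block.samples + 50.0, block.fs)
        metrics_b, _, _ = ephys.process_recording(shifted)
        for a, b in zip(metrics_a, metrics_b):
            if a.active:
                assert a.vpp_mean == pytest.approx(b.vpp_mean, rel=1e-5)
                assert a.snr == pytest.approx(b.snr, rel=1e-5)
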