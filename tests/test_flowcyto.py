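"""Gating, doublet discrimination, peak calling and genome-size estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from porphyra import flowcyto as fc
from porphyra.synthetic import FlowParams, SimConfig, simulate_flow_sample


def _events(fl, ssc=None, height=None):
    n = len(fl)
    return fc.EventTable(
        "s1",
        pd.DataFrame(
            {
                "fl": np.asarray(fl, float),
                "pulse_height": np.asarray(
                    height if height is not None else np.asarray(fl) / 1.2, float
                ),
                "ssc": np.asarray(ssc if ssc is not None else np.full(n, 2.5), float),
                "fsc": np.full(n, 2.0),
                "time": np.arange(n, dtype=float),
            }
        ),
    )


class TestGating:
    def test_identity_gate_keeps_everything(self):
        ev = _events([10, 100, 500])
        out = fc.gate_events(ev, (0, 1023), (0, 5))
        assert len(out) == len(ev)
        pd.testing.assert_frame_equal(out.data, ev.data)

    def test_membership_oracle_on_simulated_debris(self, rng):
        cfg = SimConfig(flow=FlowParams(events_per_sample=3000, debris_fraction=0.10))
        ev, truth = simulate_flow_sample([3], cfg, rng)
        region = ((20.0, 1023.0), (1.8, 5.0))
        inside = (
            (ev.data["fl"] >= region[0][0])
            & (ev.data["fl"] <= region[0][1])
            & (ev.data["ssc"] >= region[1][0])
            & (ev.data["ssc"] <= region[1][1])
        )
        gated = fc.gate_events(ev, *region)
        assert len(gated) == int(inside.sum())
        # the gate removes predominantly debris
        kept_labels = truth.labels[inside.to_numpy()]
        assert (kept_labels == "debris").mean() < 0.02

    def test_zero_area_region_rejected(self):
        ev = _events([10, 20])
        with pytest.raises(fc.GatingError):
            fc.gate_events(ev, (100, 100), (0, 5))

    def test_empty_gate_signals_misset_region(self):
        ev = _events([10, 20])
        with pytest.raises(fc.GatingError, match="mis-set"):
            fc.gate_events(ev, (900, 1000), (0, 5))


class TestDoublets:
    def test_singlets_untouched(self):
        ev = _events([100, 110, 120])
        out, removed = fc.filter_doublets(ev, max_ratio=2.0)
        assert removed == 0.0
        assert len(out) == 3

    def test_injected_doublets_removed_by_label(self, rng):
        cfg = SimConfig(
            flow=FlowParams(events_per_sample=2000, doublet_fraction=0.05)
        )
        ev, truth = simulate_flow_sample([3], cfg, rng)
        out, removed = fc.filter_doublets(ev)
        is_doublet = truth.labels == "doublet"
        # every doublet removed, and little else
        kept_ids = set(out.data["time"])
        doublet_ids = set(ev.data["time"][is_doublet[: len(ev.data)]])
        assert not (kept_ids & doublet_ids)
        assert removed == pytest.approx(is_doublet.mean(), abs=0.02)

    def test_infinite_threshold_is_identity(self):
        ev = _events([100, 200, 400], height=[80, 80, 80])
        out, removed = fc.filter_doublets(ev, max_ratio=np.inf)
        assert len(out) == 3 and removed == 0.0


class TestPeakCalling:
    def test_single_gaussian_recovered_within_one_percent(self, rng):
        fl = rng.normal(720, 0.03 * 720, size=3000)
        peaks = fc.call_peaks_events(_events(fl))
        assert len(peaks) == 1
        assert abs(peaks[0].mean_fl - 720) / 720 < 0.01
        assert peaks[0].cv == pytest.approx(3.0, abs=1.0)

    def test_two_gaussians_mean_ratio(self, rng):
        fl = np.concatenate(
            [rng.normal(100, 4.0, size=1500), rng.normal(200, 8.0, size=1500)]
        )
        peaks = fc.call_peaks_events(_events(fl))
        assert len(peaks) == 2
        ratio = peaks[1].mean_fl / peaks[0].mean_fl
        assert ratio == pytest.approx(2.0, abs=0.05)

    def test_uniform_noise_raises(self, rng):
        fl = rng.uniform(0, 1023, size=2000)
        with pytest.raises(fc.NoPeaksError):
            fc.call_peaks_events(_events(fl))

    def test_histogram_path_matches_event_path(self, rng):
        fl = rng.normal(300, 12.0, size=4000)
        ev = _events(fl)
        hist = fc.build_histogram(ev, n_bins=512)
        assert hist.total == len(ev)
        p_hist = fc.call_peaks(hist)
        p_ev = fc.call_peaks_events(ev)
        assert len(p_hist) == len(p_ev) == 1
        assert p_hist[0].mean_fl == pytest.approx(p_ev[0].mean_fl, rel=0.01)

    def test_too_few_events_rejected(self, rng):
        fl = rng.normal(300, 10, size=100)
        with pytest.raises(fc.NoPeaksError, match="minimum"):
            fc.call_peaks_events(_events(fl))


def _peak(mean, prop=0.5, cv=3.0):
    return fc.NucleiPeak(mean_fl=mean, cv=cv, count=1000, proportion=prop)


class TestStandardAndSize:
    def test_channel_720_convention(self, standard):
        std_peak, sample = fc.identify_standard([_peak(72), _peak(720)], standard)
        assert std_peak.mean_fl == 720 and std_peak.phase == "standard"
        assert [p.mean_fl for p in sample] == [72]

    def test_no_peak_near_expected_channel(self, standard):
        with pytest.raises(fc.StandardNotFoundError):
            fc.identify_standard([_peak(300), _peak(310)], standard, tolerance=0.10)

    def test_nearest_within_tolerance_wins(self, standard):
        std_peak, sample = fc.identify_standard([_peak(700), _peak(1400)], standard)
        assert std_peak.mean_fl == 700
        assert [p.mean_fl for p in sample] == [1400]

    def test_unit_ratio_returns_standard_2c(self, standard):
        assert fc.estimate_genome_size(_peak(720), _peak(720), standard) == 1.96

    def test_printed_formula_arithmetic(self, standard):
        size = fc.estimate_genome_size(_peak(73.5), _peak(720), standard)
        assert size == pytest.approx(0.200, abs=0.0005)

    @given(st.floats(min_value=1.0, max_value=500.0))
    def test_linearity_in_sample_mean(self, mean):
        std = fc.StandardRef("s", 1.96, 720)
        one = fc.estimate_genome_size(_peak(mean), _peak(720), std)
        two = fc.estimate_genome_size(_peak(2 * mean), _peak(720), std)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_tetraploid_sample_estimate(self, standard, rng):
        # a 0.38 pg tetraploid-like sample: peak at 0.38/1.96*720
        chan = 0.38 / 1.96 * 720
        fl = np.concatenate(
            [rng.normal(chan, 0.04 * chan, 1500), rng.normal(720, 0.03 * 720, 500)]
        )
        peaks = fc.call_peaks_events(_events(fl))
        std_peak, sample = fc.identify_standard(peaks, standard)
        size = fc.estimate_genome_size(sample[0], std_peak, standard)
        assert size == pytest.approx(0.38, abs=0.02)


class TestG2Labelling:
    def test_minor_double_peak_is_g2(self):
        out = fc.label_g2([_peak(100, 0.8), _peak(200, 0.1)])
        assert [p.phase for p in out] == ["G1", "G2"]

    def test_balanced_double_peak_is_mixoploid_not_g2(self):
        out = fc.label_g2([_peak(100, 0.45), _peak(200, 0.40)])
        assert [p.phase for p in out] == ["G1", "G1"]

    def test_merged_companion_between_adjacent_peaks_is_g2(self):
        # one small component fitted between 2x110 and 2x147
        out = fc.label_g2([_peak(110, 0.4), _peak(147, 0.4), _peak(257, 0.05)])
        assert [p.phase for p in out] == ["G1", "G1", "G2"]

    def test_g1_g2_pair_never_reports_g2_as_ploidy(self, standard, rng):
        cfg = SimConfig(flow=FlowParams(g2_fraction=0.10))
        ev, truth = simulate_flow_sample(
            [4], cfg, rng, sample_id="b:vegetative"
        )
        peaks, call = fc.analyze_sample(ev, standard)
        assert len(call.sizes_pg) == 1  # only the G1 peak is sized
        g2 = [p for p in peaks if p.phase == "G2"]
        assert len(g2) == 1
        assert g2[0].mean_fl == pytest.approx(
            2 * truth.g1_channels[4], rel=0.05
        )


class TestQC:
    def test_cv_thresholds(self):
        call = fc.GenomeSizeCall("s", "vegetative", [0.2, 0.4], [2.5, 3.1])
        assert fc.qc_sample(call, max_cv=5.0).qc_pass
        call = fc.GenomeSizeCall("s", "vegetative", [0.2], [8.0])
        assert not fc.qc_sample(call, max_cv=5.0).qc_pass

    def test_replicate_cv_hand_computed(self):
        # sd(0.19,0.20,0.21)/mean = 0.01/0.20 = 5.0%
        call = fc.GenomeSizeCall("s", "male_gamete", [0.2], [2.0])
        out = fc.qc_sample(call, replicate_sizes=[0.19, 0.20, 0.21], max_replicate_cv=6.0)
        assert out.qc_pass
        assert any("replicate_cv=5.00%" in n for n in out.notes)
        out = fc.qc_sample(call, replicate_sizes=[0.19, 0.20, 0.21], max_replicate_cv=4.0)
        assert not out.qc_pass


class TestPipelineInvariants:
    def test_filters_never_increase_counts_and_are_idempotent(self, rng):
        cfg = SimConfig(flow=FlowParams(doublet_fraction=0.03))
        ev, _ = simulate_flow_sample([3, 4], cfg, rng)
        gated = fc.gate_events(ev, (20, 1023), (1.5, 5))
        assert len(gated) <= len(ev)
        again = fc.gate_events(gated, (20, 1023), (1.5, 5))
        assert len(again) == len(gated)
        ratio = 1.5 * float(
            (gated.data["fl"] / gated.data["pulse_height"]).median()
        )
        once, _ = fc.filter_doublets(gated, ratio)
        twice, removed = fc.filter_doublets(once, ratio)
        assert len(once) <= len(gated)
        assert len(twice) == len(once) and removed == 0.0
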