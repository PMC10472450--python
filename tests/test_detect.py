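import numpy as np
import pytest

from bcgkit import (
    BeatAnnotations,
    FusionState,
    RunConfig,
    SimConfig,
    detect_ijk,
    hard_mode,
    interpolate_outliers,
    locate_i_k_waves,
    locate_j_waves,
    refine_to_raw,
    simulate_record,
)
from bcgkit.pipeline import evaluate_against_truth
from bcgkit.records import PeakList, SignalRecord

FS = 250.0


def peaks(indices, source):
    idx = np.asarray(indices, dtype=np.int64)
    return PeakList(idx, np.ones(idx.size), source=source)


def fresh_state(history=(), region=10):
    st = FusionState(region=region, maxlen=9)
    for h in history:
        st.history.append(h)
    return st


class TestJFusionRules:
    def test_case1_single_peak_in_region(self):
        js, st = locate_j_waves(peaks([500], "stft"), peaks([495, 530], "imf"),
                                FS, state=fresh_state())
        assert js.tolist() == [495]  # 20 ms in-region; 530 is 120 ms away
        assert st.counts["case1"] == 1

    def test_case2_follows_left_trend(self):
        js, st = locate_j_waves(peaks([500], "stft"), peaks([470, 530], "imf"),
                                FS, state=fresh_state(history=[-12] * 5))
        assert js.tolist() == [470]
        assert st.counts["case2"] == 1
        assert st.counts["override"] == 0  # equidistant: no 2x correction

    def test_case2_follows_right_trend(self):
        js, _ = locate_j_waves(peaks([500], "stft"), peaks([470, 530], "imf"),
                               FS, state=fresh_state(history=[12] * 5))
        assert js.tolist() == [530]

    def test_case2_twice_distance_override(self):
        # trend says left (30 samples away) but right is only 12: 30 > 2*12
        js, st = locate_j_waves(peaks([500], "stft"), peaks([470, 512], "imf"),
                                FS, state=fresh_state(history=[-12] * 5))
        assert js.tolist() == [512]
        assert st.counts["override"] == 1

    def test_case2_no_history_takes_nearest(self):
        js, _ = locate_j_waves(peaks([500], "stft"), peaks([470, 520], "imf"),
                               FS, state=fresh_state())
        assert js.tolist() == [520]

    def test_case3_both_in_region_nearest_wins(self):
        js, st = locate_j_waves(peaks([500], "stft"), peaks([494, 505], "imf"),
                                FS, state=fresh_state())
        assert js.tolist() == [505]
        assert st.counts["case3"] == 1

    def test_case3_equidistant_tie_goes_left(self):
        js, _ = locate_j_waves(peaks([500], "stft"), peaks([492, 508], "imf"),
                               FS, state=fresh_state())
        assert js.tolist() == [492]

    def test_count_trend_rule_variant(self):
        cfg = RunConfig(trend_rule="count")
        st = fresh_state(history=[-30, -25, 8, -28, 9])  # 3 left vs 2 right
        js, _ = locate_j_waves(peaks([500], "stft"), peaks([470, 530], "imf"),
                               FS, config=cfg, state=st)
        assert js.tolist() == [470]

    def test_one_sided_fall_through(self):
        js, st = locate_j_waves(peaks([500], "stft"), peaks([530], "imf"),
                                FS, state=fresh_state())
        assert js.tolist() == [530]
        assert st.counts["one_sided"] == 1

    def test_duplicate_choices_collapse(self):
        js, _ = locate_j_waves(peaks([500, 560], "stft"), peaks([530], "imf"),
                               FS, state=fresh_state())
        assert js.tolist() == [530]

    def test_empty_imf_list(self):
        js, _ = locate_j_waves(peaks([500], "stft"), peaks([], "imf"),
                               FS, state=fresh_state())
        assert js.size == 0

    def test_fusion_never_invents_positions(self, rng):
        for _ in range(50):
            stft_idx = np.sort(rng.choice(5000, size=8, replace=False))
            stft_idx = stft_idx[np.insert(np.diff(stft_idx) > 80, 0, True)]
            imf_idx = np.sort(rng.choice(5000, size=30, replace=False))
            js, _ = locate_j_waves(peaks(stft_idx, "stft"), peaks(imf_idx, "imf"),
                                   FS, state=fresh_state())
            assert set(js.tolist()) <= set(imf_idx.tolist())
            assert js.size <= stft_idx.size


def synth_w(n=500, j=250, fs=FS):
    """A single clean W complex (I/J/K gaussian lobes) on an IMF-like trace."""
    t = np.arange(n)
    x = np.zeros(n)
    for centre, amp in ((j - 20, -0.6), (j, 1.0), (j + 20, -0.65)):
        x += amp * np.exp(-0.5 * ((t - centre) / 5.0) ** 2)
    return x


class TestIKSearch:
    def test_clean_w_recovers_truth(self):
        x = synth_w()
        ann = locate_i_k_waves([250], x, FS, threshold=0.5)
        (i_idx, j_idx, k_idx), = ann.beat_tuples()
        assert abs(i_idx - 230) <= 2
        assert j_idx == 250
        assert abs(k_idx - 270) <= 2
        assert ann.valid[0]

    def test_monotone_side_yields_absent_k(self):
        x = synth_w()
        x[251:] = x[250] - 0.001 * np.arange(1, x.size - 250)  # decay, no minimum
        ann = locate_i_k_waves([250], x, FS, threshold=0.5)
        (_, _, k_idx), = ann.beat_tuples()
        assert k_idx is None
        assert not ann.valid[0]

    def test_minimum_without_zero_crossing_skipped(self):
        t = np.arange(500.0)
        x = np.exp(-0.5 * ((t - 250) / 5.0) ** 2)          # J at 250
        x += 0.4 * np.exp(-0.5 * ((t - 262) / 3.0) ** 2)   # shallow positive dip after J
        x += -0.7 * np.exp(-0.5 * ((t - 280) / 5.0) ** 2)  # true K beyond a crossing
        ann = locate_i_k_waves([250], x, FS, threshold=0.5)
        (_, _, k_idx), = ann.beat_tuples()
        assert k_idx is not None
        assert abs(k_idx - 280) <= 2  # not the crossing-free dip near 256

    def test_shallow_minimum_rejected_by_depth(self):
        t = np.arange(500.0)
        x = np.exp(-0.5 * ((t - 250) / 5.0) ** 2)
        x += -0.1 * np.exp(-0.5 * ((t - 270) / 5.0) ** 2)  # crosses zero but shallow
        ann = locate_i_k_waves([250], x, FS, threshold=0.5)
        (_, _, k_idx), = ann.beat_tuples()
        assert k_idx is None  # -0.1 is above the -0.25 depth requirement


class TestRefineToRaw:
    def test_shift_to_nearby_raw_maximum(self):
        imf = synth_w()
        raw = np.roll(imf, 1)  # raw extrema sit one sample to the right
        ann = locate_i_k_waves([250], imf, FS, threshold=0.5)
        refined = refine_to_raw(ann, raw, FS, refine_ms=12.0)
        (i0, j0, k0), = ann.beat_tuples()
        (i1, j1, k1), = refined.beat_tuples()
        assert (i1, j1, k1) == (i0 + 1, j0 + 1, k0 + 1)

    def test_identity_when_raw_equals_imf(self):
        imf = synth_w()
        ann = locate_i_k_waves([250], imf, FS, threshold=0.5)
        refined = refine_to_raw(ann, imf, FS)
        assert refined.beat_tuples() == ann.beat_tuples()

    def test_refinement_does_not_degrade_on_average(self, clean_sim):
        record, truth = clean_sim
        bcg = record.channel("bcg")
        j_true = truth.annotations.j_indices
        rng = np.random.default_rng(3)
        jitter = rng.integers(-2, 3, size=j_true.size)
        perturbed = BeatAnnotations(
            beats=[(None, j + d, None) for j, d in zip(j_true, jitter)],
            valid=[True] * j_true.size, fs=FS)
        refined = refine_to_raw(perturbed, bcg, FS)
        err_before = np.abs(perturbed.j_indices - j_true).mean()
        err_after = np.abs(refined.j_indices - j_true).mean()
        assert err_after <= err_before


class TestOutlierInterpolation:
    def make_ann(self, jj_s):
        j = np.concatenate([[0.0], np.cumsum(jj_s)]) * FS + 1000
        return BeatAnnotations(beats=[(None, int(v), None) for v in j],
                               valid=[True] * (len(jj_s) + 1), fs=FS)

    def test_long_interval_terminal_j_interpolated(self):
        ann = self.make_ann([0.8, 0.8, 1.9, 0.8, 0.8])
        out = interpolate_outliers(ann, FS)
        assert out.n_beats == ann.n_beats
        bad = 3  # terminal beat of the 1.9 s interval
        assert not out.valid[bad]
        expect = (ann.j_indices[bad - 1] + ann.j_indices[bad + 1]) / 2
        assert out.j_indices[bad] == int(round(expect))

    def test_regular_rhythm_unchanged(self):
        ann = self.make_ann([0.8] * 10)
        out = interpolate_outliers(ann, FS)
        np.testing.assert_array_equal(out.j_indices, ann.j_indices)
        assert out.valid.all()

    def test_too_few_beats_warns_and_passes_through(self):
        ann = self.make_ann([0.8])
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = interpolate_outliers(ann, FS)
        np.testing.assert_array_equal(out.j_indices, ann.j_indices)


class TestEndToEnd:
    def test_default_record_recovery(self, default_detection):
        record, truth, ann, report = default_detection
        metrics = evaluate_against_truth(ann, truth.annotations.j_indices, record.fs)
        assert metrics["hit_rate_pct"] >= 95.0
        assert metrics["n_detected"] <= truth.annotations.n_beats + 3

    def test_determinism(self):
        cfg = SimConfig(duration_s=30.0, seed=21)
        record, _ = simulate_record(cfg)
        a = detect_ijk(record, RunConfig(rng_seed=21))
        b = detect_ijk(record, RunConfig(rng_seed=21))
        assert a.beat_tuples() == b.beat_tuples()
        np.testing.assert_array_equal(a.valid, b.valid)

    def test_zero_record_yields_no_beats(self):
        record = SignalRecord(FS, {"bcg": np.zeros(int(30 * FS))})
        ann = detect_ijk(record)
        assert ann.n_beats == 0

    def test_hard_mode_exercises_trend_branch(self):
        record, truth = simulate_record(hard_mode(SimConfig(duration_s=30.0, seed=7)))
        ann, report = detect_ijk(record, RunConfig(rng_seed=7), return_report=True)
        assert report.counts["case2"] >= 1
        metrics = evaluate_against_truth(ann, truth.annotations.j_indices, record.fs)
        assert metrics["hit_rate_pct"] >= 90.0
        # drift consistency: large offsets overwhelmingly share one sign
        offs = np.asarray(report.offsets)
        big = offs[np.abs(offs) > 10]
        if big.size >= 10:
            frac = max((big > 0).mean(), (big < 0).mean())
            assert frac >= 0.9
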