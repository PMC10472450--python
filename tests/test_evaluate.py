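import numpy as np
import pandas as pd
import pytest

from bcgkit import (
    BeatAnnotations,
    agreement,
    bandpass_bcg,
    compare_morphology,
    ecg_referenced_ijk,
    pair_beats,
    paired_heart_rates,
    summarize_subjects,
)
from bcgkit.records import PeakList

FS = 250.0


class TestAgreement:
    def test_mae_rmse_worked_example(self):
        rep = agreement([1, 2, 3], [1, 2, 4])
        assert rep.mae == pytest.approx(1 / 3)
        assert rep.rmse == pytest.approx(np.sqrt(1 / 3))
        assert rep.mae_pct == pytest.approx(100 * (1 / 3) / 2)

    def test_identical_sequences(self):
        rep = agreement([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.mae == 0 and rep.rmse == 0 and rep.bias == 0
        assert rep.loa == (0.0, 0.0)
        assert rep.p_value == 1.0

    def test_paired_t_textbook_fixture(self):
        rep = agreement([0, 0, 0, 0], [2, 0, 2, 0])  # differences 2,0,2,0
        assert rep.bias == pytest.approx(1.0)
        sd = np.std([2, 0, 2, 0], ddof=1)
        assert rep.t_stat == pytest.approx(1.0 / (sd / 2), abs=1e-6)
        assert rep.loa[0] == pytest.approx(1.0 - 1.96 * sd)
        assert rep.loa[1] == pytest.approx(1.0 + 1.96 * sd)

    def test_bias_antisymmetric_mae_symmetric(self, rng):
        a = rng.standard_normal(50)
        b = a + rng.standard_normal(50) * 0.2
        fwd = agreement(a, b)
        rev = agreement(b, a)
        assert fwd.bias == pytest.approx(-rev.bias)
        assert fwd.mae == pytest.approx(rev.mae)
        assert fwd.rmse == pytest.approx(rev.rmse)

    def test_mae_never_exceeds_rmse(self, rng):
        for _ in range(20):
            a = rng.standard_normal(30)
            b = rng.standard_normal(30)
            rep = agreement(a, b)
            assert rep.mae <= rep.rmse + 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            agreement([1, 2], [1, 2, 3])


def ann_from_times(times_s, fs=FS):
    return BeatAnnotations(
        beats=[(None, int(round(t * fs)), None) for t in times_s],
        valid=[True] * len(times_s), fs=fs)


def rpeaks_from_times(times_s, fs=FS):
    idx = np.asarray([int(round(t * fs)) for t in times_s])
    return PeakList(idx, np.ones(idx.size), source="raw")


class TestPairBeats:
    def test_full_match(self):
        m = pair_beats(rpeaks_from_times([1, 2, 3]),
                       ann_from_times([1.25, 2.25, 3.25]), FS)
        assert len(m.pairs) == 3
        assert m.coverage_pct == pytest.approx(100.0)
        assert m.n_false == 0

    def test_missing_beat_reduces_coverage(self):
        m = pair_beats(rpeaks_from_times([1, 2, 3]),
                       ann_from_times([1.25, 3.25]), FS)
        assert len(m.pairs) == 2
        assert m.coverage_pct == pytest.approx(100 * 2 / 3, abs=0.1)

    def test_two_js_in_one_window_nearer_matched(self):
        m = pair_beats(rpeaks_from_times([1.0, 9.0]),
                       ann_from_times([1.05, 1.38, 9.25]), FS)
        matched_j = {jp for _, jp in m.pairs}
        assert 0 in matched_j      # 1.05 is nearer to R at 1.0 than 1.38
        assert 1 not in matched_j
        assert m.n_false == 1

    def test_matching_is_one_to_one(self):
        m = pair_beats(rpeaks_from_times([1.0, 1.4]),
                       ann_from_times([1.25]), FS)
        assert len(m.pairs) == 1


class TestEcgReferencedDetector:
    def test_template_offset_matches_r_to_j(self, clean_sim, clean_config):
        record, truth = clean_sim
        filtered = bandpass_bcg(record)
        r = PeakList(truth.r_indices, np.ones(truth.r_indices.size), source="raw")
        ref = ecg_referenced_ijk(filtered, r)
        offsets = (ref.j_indices - truth.r_indices[:ref.n_beats]) / FS
        assert np.allclose(offsets, clean_config.r_to_j_s, atol=2 / FS)

    def test_per_beat_reference_matches_truth(self, clean_sim):
        record, truth = clean_sim
        filtered = bandpass_bcg(record)
        r = PeakList(truth.r_indices, np.ones(truth.r_indices.size), source="raw")
        ref = ecg_referenced_ijk(filtered, r)
        j_true = truth.annotations.j_indices[:ref.n_beats]
        assert np.all(np.abs(ref.j_indices - j_true) <= 2)

    def test_template_robust_to_one_corrupt_epoch(self, clean_sim):
        record, truth = clean_sim
        filtered = bandpass_bcg(record)
        r = PeakList(truth.r_indices, np.ones(truth.r_indices.size), source="raw")
        ref_clean = ecg_referenced_ijk(filtered, r)
        x = filtered.channel("bcg").copy()
        lo = int(truth.r_indices[5])
        x[lo:lo + 150] += np.random.default_rng(0).standard_normal(150) * 2.0
        corrupt = filtered.with_channel("bcg", x)
        ref_corrupt = ecg_referenced_ijk(corrupt, r)
        clean_offsets = ref_clean.j_indices - truth.r_indices[:ref_clean.n_beats]
        corrupt_offsets = ref_corrupt.j_indices - truth.r_indices[:ref_corrupt.n_beats]
        assert abs(np.median(clean_offsets) - np.median(corrupt_offsets)) <= 1

    def test_too_few_beats_rejected(self, clean_sim):
        record, truth = clean_sim
        filtered = bandpass_bcg(record)
        r = PeakList(truth.r_indices[:5], np.ones(5), source="raw")
        with pytest.raises(ValueError, match="epochs"):
            ecg_referenced_ijk(filtered, r)


class TestCompareMorphology:
    def test_identical_annotations_zero_error(self, clean_sim):
        record, truth = clean_sim
        filtered = bandpass_bcg(record)
        reports = compare_morphology(truth.annotations, truth.annotations, filtered)
        assert reports["ij_amplitude"].mae == 0.0
        assert reports["ik_interval_ms"].mae == 0.0

    def test_shifted_j_amplitude_error_matches_signal_slope(self, clean_sim):
        record, truth = clean_sim
        filtered = bandpass_bcg(record)
        x = filtered.channel("bcg")
        tuples = truth.annotations.beat_tuples()
        shifted = BeatAnnotations(
            beats=[(i, j + 1, k) for i, j, k in tuples],
            valid=[True] * len(tuples), fs=FS)
        reports = compare_morphology(truth.annotations, shifted, filtered)
        expected = np.mean([abs(x[j + 1] - x[j]) for _, j, _ in tuples])
        assert reports["ij_amplitude"].mae == pytest.approx(expected, rel=1e-9)
        assert reports["ik_interval_ms"].mae == 0.0

    def test_incomplete_beats_excluded(self, clean_sim):
        record, truth = clean_sim
        filtered = bandpass_bcg(record)
        tuples = truth.annotations.beat_tuples()
        gappy = BeatAnnotations(
            beats=[(None, j, None) if b == 2 else (i, j, k)
                   for b, (i, j, k) in enumerate(tuples)],
            valid=[True] * len(tuples), fs=FS)
        reports = compare_morphology(truth.annotations, gappy, filtered)
        assert reports["ij_amplitude"].n_pairs == len(tuples) - 1


class TestSummarizeSubjects:
    def test_single_row_is_identity(self):
        df = pd.DataFrame({"mae": [1.23], "rmse": [2.5]})
        out = summarize_subjects(df)
        assert out["mae"] == 1.23
        assert out["rmse"] == 2.5

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_subjects(pd.DataFrame({"mae": []}))

    def test_plain_column_means(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 4.0]})
        assert summarize_subjects(df)["a"] == pytest.approx(2.33)


class TestPipelineAgreement:
    def test_default_record_hr_agreement(self, default_detection):
        from bcgkit import detect_r_peaks, preprocess_ecg

        record, truth, ann, _ = default_detection
        ecg = preprocess_ecg(record)
        r = detect_r_peaks(ecg)
        hr_ref, hr_test, matching = paired_heart_rates(r, ann, FS)
        rep = agreement(hr_ref, hr_test)
        assert rep.mae <= 2.0
        assert matching.coverage_pct >= 90.0
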