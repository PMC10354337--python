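"""Synthetic cohort generator and reviewer simulator."""

import numpy as np
import pytest

from ictalflow.synthdata import (ChannelAnnotation, ChannelTruth, CohortConfig,
                                 IEEGRecord, ReviewerProfile,
                                 annotations_from_csv, annotations_to_csv,
                                 generate_cohort, generate_record, read_cohort_h5,
                                 read_edf, simulate_reviewers, truths_from_csv,
                                 truths_to_csv, write_cohort_h5, write_edf)

FS = 250.0


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


@pytest.fixture(scope="module")
def one_record():
    cfg = CohortConfig(n_patients=1, records_per_patient=1, seed=3)
    rng = np.random.default_rng(5)
    rec, truths = generate_record(cfg, "P000", {0: 30.0, 2: 25.0}, rng,
                                  record_id="P000_R00")
    return cfg, rec, truths


class TestGenerateRecord:
    def test_seizure_channel_rms_ratio(self, one_record):
        """Post-onset activity reaches >= 3x the pre-onset RMS within 5 s."""
        _, rec, _ = one_record
        x = rec.channels[0]
        post = _rms(x[int(35 * FS):int(40 * FS)])
        pre = _rms(x[:int(25 * FS)])
        assert post / pre >= 3.0

    def test_non_seizure_channel_has_no_burst(self, one_record):
        """Windowed-RMS scan: no 5-s window exceeds 3x the median window."""
        _, rec, _ = one_record
        for ch in (1, 3):
            x = rec.channels[ch]
            w = int(5 * FS)
            rms = [_rms(x[i:i + w]) for i in range(0, len(x) - w + 1, w)]
            assert max(rms) / np.median(rms) < 3.0

    def test_truth_invariants(self, one_record):
        _, rec, truths = one_record
        assert len(rec.channels) == 4
        assert all(len(c) == 22500 for c in rec.channels)
        for t in truths:
            assert t.is_seizure == (t.onset_time_s is not None)

    def test_deterministic_under_seed(self):
        cfg = CohortConfig(n_patients=1, records_per_patient=1, seed=3)
        recs = []
        for _ in range(2):
            rng = np.random.default_rng(11)
            rec, _ = generate_record(cfg, "P000", {1: 40.0}, rng,
                                     record_id="r")
            recs.append(rec)
        for a, b in zip(recs[0].channels, recs[1].channels):
            assert np.array_equal(a, b)

    def test_rejects_bad_specs(self):
        cfg = CohortConfig(n_patients=1, records_per_patient=1)
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            generate_record(cfg, "P0", {0: 95.0}, rng)  # onset beyond record
        with pytest.raises(ValueError):
            generate_record(cfg, "P0", {7: 30.0}, rng)  # channel out of range
        with pytest.raises(ValueError):
            IEEGRecord(record_id="r", patient_id="p", channels=[])


class TestGenerateCohort:
    def test_counts(self):
        cfg = CohortConfig(n_patients=3, records_per_patient=4, seed=0)
        records, truths = generate_cohort(cfg)
        assert len(records) == 12
        assert len(truths) == 12 * 4

    def test_single_record(self):
        records, _ = generate_cohort(
            CohortConfig(n_patients=1, records_per_patient=1, seed=0))
        assert len(records) == 1

    def test_zero_fraction_means_no_seizures(self):
        _, truths = generate_cohort(CohortConfig(
            n_patients=2, records_per_patient=3, seizure_record_fraction=0.0,
            seed=1))
        assert not any(t.is_seizure for t in truths)

    def test_record_prevalence_matches_fraction(self):
        """Seizure-record share within 2 points of the target at ~1000 channels."""
        cfg = CohortConfig(n_patients=125, records_per_patient=2,
                           seizure_record_fraction=0.35, seed=9)
        records, truths = generate_cohort(cfg)
        sz_records = {t.record_id for t in truths if t.is_seizure}
        prevalence = len(sz_records) / len(records)
        assert abs(prevalence - 0.35) <= 0.02

    def test_cohort_determinism(self):
        cfg = CohortConfig(n_patients=2, records_per_patient=2, seed=5)
        r1, t1 = generate_cohort(cfg)
        r2, t2 = generate_cohort(cfg)
        assert [t.onset_time_s for t in t1] == [t.onset_time_s for t in t2]
        assert all(np.array_equal(a.channels[i], b.channels[i])
                   for a, b in zip(r1, r2) for i in range(4))

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ValueError):
            CohortConfig(n_patients=0)

    def test_trigger_follows_onset(self):
        cfg = CohortConfig(n_patients=6, records_per_patient=2,
                           seizure_record_fraction=1.0, seed=2)
        records, truths = generate_cohort(cfg)
        onset = {t.record_id: t.onset_time_s for t in truths if t.is_seizure}
        for rec in records:
            first = min(t.onset_time_s for t in truths
                        if t.record_id == rec.record_id and t.is_seizure)
            assert rec.trigger_time_s == pytest.approx(
                min(first + 30.0, rec.duration_s))


def _flat_truths(n, is_seizure, ambiguity=0.0, onset=30.0):
    return [ChannelTruth(f"r{i}", 0, is_seizure,
                         onset if is_seizure else None, ambiguity)
            for i in range(n)]


class TestSimulateReviewers:
    def test_perfect_profile_reproduces_truth(self):
        truths = _flat_truths(50, True) + _flat_truths(50, False)
        prof = ReviewerProfile("R", sensitivity=1.0, specificity=1.0,
                               unsure_rate=0.0, onset_jitter_sd_s=0.0)
        anns = simulate_reviewers(truths, [prof], np.random.default_rng(0))
        for t, a in zip(truths, anns):
            assert a.label == ("seizure" if t.is_seizure else "non_seizure")
            if t.is_seizure:
                assert a.onset_time_s == pytest.approx(30.0)

    def test_full_ambiguity_gives_coin_flip(self):
        """ambiguity = 1 pulls the seizure-label rate to 0.5 on true seizures."""
        n = 4000
        truths = _flat_truths(n, True, ambiguity=1.0)
        prof = ReviewerProfile("R", sensitivity=0.95, specificity=0.95,
                               unsure_rate=0.0)
        anns = simulate_reviewers(truths, [prof], np.random.default_rng(1))
        rate = np.mean([a.label == "seizure" for a in anns])
        # 4 binomial SEs around 0.5
        assert abs(rate - 0.5) <= 4 * np.sqrt(0.25 / n)

    def test_unsure_count_in_binomial_interval(self):
        """unsure_rate 0.02 on 4,000 channels -> count near 80."""
        truths = _flat_truths(4000, False)
        prof = ReviewerProfile("R", unsure_rate=0.02)
        anns = simulate_reviewers(truths, [prof], np.random.default_rng(2))
        n_unsure = sum(a.label == "unsure" for a in anns)
        # 99% binomial interval around 80
        sd = np.sqrt(4000 * 0.02 * 0.98)
        assert 80 - 2.58 * sd <= n_unsure <= 80 + 2.58 * sd

    def test_label_marginals_recover_profile(self):
        """With zero ambiguity the empirical rates converge to the profile."""
        n = 4000
        truths = _flat_truths(n, True) + _flat_truths(n, False)
        prof = ReviewerProfile("R", sensitivity=0.9, specificity=0.8,
                               unsure_rate=0.0)
        anns = simulate_reviewers(truths, [prof], np.random.default_rng(3))
        sz = [a.label == "seizure" for a in anns[:n]]
        fp = [a.label == "seizure" for a in anns[n:]]
        assert abs(np.mean(sz) - 0.9) <= 3 * np.sqrt(0.9 * 0.1 / n)
        assert abs(np.mean(fp) - 0.2) <= 3 * np.sqrt(0.2 * 0.8 / n)

    def test_onset_jitter_sd_recovered(self):
        truths = _flat_truths(800, True, onset=40.0)
        prof = ReviewerProfile("R", sensitivity=1.0, unsure_rate=0.0,
                               onset_jitter_sd_s=1.5)
        anns = simulate_reviewers(truths, [prof], np.random.default_rng(4))
        deltas = [a.onset_time_s - 40.0 for a in anns if a.label == "seizure"]
        assert len(deltas) >= 500
        assert abs(np.std(deltas) - 1.5) <= 0.15 * 1.5

    def test_onsets_on_tenth_second_grid(self):
        truths = _flat_truths(100, True, onset=33.337)
        prof = ReviewerProfile("R", sensitivity=1.0, unsure_rate=0.0,
                               onset_jitter_sd_s=0.7)
        anns = simulate_reviewers(truths, [prof], np.random.default_rng(5))
        for a in anns:
            if a.onset_time_s is not None:
                assert round(a.onset_time_s * 10) == pytest.approx(
                    a.onset_time_s * 10)

    def test_before_record_start_flag(self):
        truths = _flat_truths(20, True, onset=2.0)
        prof = ReviewerProfile("R", sensitivity=1.0, unsure_rate=0.0,
                               onset_jitter_sd_s=0.0, onset_bias_s=-5.0)
        anns = simulate_reviewers(truths, [prof], np.random.default_rng(6))
        assert all(a.onset_before_record_start for a in anns)
        assert all(a.onset_time_s is None for a in anns)

    def test_rejects_invalid_profiles(self):
        with pytest.raises(ValueError):
            ReviewerProfile("R", sensitivity=0.0)
        with pytest.raises(ValueError):
            ReviewerProfile("R", unsure_rate=1.0)
        with pytest.raises(ValueError):
            simulate_reviewers([], [], np.random.default_rng(0))


class TestIO:
    def test_edf_round_trip_within_quantization(self, one_record, tmp_path):
        _, rec, _ = one_record
        path = tmp_path / "rec.edf"
        write_edf(rec, path)
        back = read_edf(path)
        assert back.record_id == rec.record_id
        assert back.patient_id == rec.patient_id
        assert back.sample_rate_hz == rec.sample_rate_hz
        for a, b in zip(rec.channels, back.channels):
            q = np.max(np.abs(a)) / 32767
            assert np.max(np.abs(np.asarray(a) - b)) <= q * 1.001

    def test_edf_readable_by_mne(self, one_record, tmp_path):
        mne = pytest.importorskip("mne")
        _, rec, _ = one_record
        path = tmp_path / "rec.edf"
        write_edf(rec, path)
        raw = mne.io.read_raw_edf(path, verbose="error")
        data = raw.get_data() * 1e6  # mne reads uV as V
        q = max(np.max(np.abs(c)) for c in rec.channels) / 32767
        assert np.max(np.abs(data - np.asarray(rec.channels))) <= 2 * q

    def test_h5_round_trip_bit_exact(self, tmp_path):
        cfg = CohortConfig(n_patients=2, records_per_patient=1, seed=1)
        records, truths = generate_cohort(cfg)
        path = tmp_path / "cohort.h5"
        write_cohort_h5(records, truths, path)
        r2, t2 = read_cohort_h5(path)
        by_id = {r.record_id: r for r in r2}
        for rec in records:
            back = by_id[rec.record_id]
            for a, b in zip(rec.channels, back.channels):
                assert np.array_equal(a, b)
        assert {(t.record_id, t.channel_index, t.is_seizure) for t in truths} \
            == {(t.record_id, t.channel_index, t.is_seizure) for t in t2}

    def test_annotation_csv_round_trip(self, tmp_path):
        anns = [
            ChannelAnnotation("R1", "r0", 0, "seizure", 30.1),
            ChannelAnnotation("R1", "r0", 1, "non_seizure"),
            ChannelAnnotation("R2", "r0", 2, "unsure"),
            ChannelAnnotation("R2", "r1", 0, "seizure",
                              onset_before_record_start=True),
        ]
        path = tmp_path / "ann.csv"
        annotations_to_csv(anns, path)
        back = annotations_from_csv(path)
        assert [(a.reviewer_id, a.record_id, a.channel_index, a.label,
                 a.onset_time_s, a.onset_before_record_start) for a in anns] \
            == [(a.reviewer_id, a.record_id, a.channel_index, a.label,
                 a.onset_time_s, a.onset_before_record_start) for a in back]

    def test_truth_csv_round_trip(self, tmp_path):
        truths = [ChannelTruth("r0", 0, True, 29.4, 0.2),
                  ChannelTruth("r0", 1, False, None, 0.8)]
        path = tmp_path / "truths.csv"
        truths_to_csv(truths, path)
        back = truths_from_csv(path)
        assert [(t.record_id, t.channel_index, t.is_seizure, t.onset_time_s)
                for t in truths] == \
            [(t.record_id, t.channel_index, t.is_seizure, t.onset_time_s)
             for t in back]
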