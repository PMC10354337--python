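"""Agreement, consensus, calibration, PR curves, BCa bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ictalflow.rater_stats import (BCaInterval, PairwiseRates,
                                   bca_interval, calibration,
                                   channel_agreement, consensus_summary,
                                   noninferiority_check, pairwise_rates,
                                   pr_curve)


def _frame(labels, start=0):
    return pd.DataFrame({
        "record_id": [f"r{start + i}" for i in range(len(labels))],
        "channel_index": 0,
        "label": labels,
    })


class TestChannelAgreement:
    def test_identical_labels(self):
        a = _frame(["seizure", "non_seizure", "seizure"])
        bd = channel_agreement(a, a)
        assert (bd.overall_pct, bd.seizure_pct, bd.nonseizure_pct) == \
            (100.0, 100.0, 100.0)

    def test_toy_breakdown(self):
        a = _frame(["seizure", "seizure", "non_seizure", "non_seizure"])
        b = _frame(["seizure", "non_seizure", "non_seizure", "seizure"])
        bd = channel_agreement(a, b)
        assert (bd.overall_pct, bd.seizure_pct, bd.nonseizure_pct) == \
            (50.0, 50.0, 50.0)

    def test_complementary_labels(self):
        a = _frame(["seizure", "non_seizure"])
        b = _frame(["non_seizure", "seizure"])
        assert channel_agreement(a, b).overall_pct == 0.0

    def test_overall_symmetric_but_classes_reference_dependent(self):
        a = _frame(["seizure", "seizure", "non_seizure"])
        b = _frame(["seizure", "non_seizure", "non_seizure"])
        ab = channel_agreement(a, b)
        ba = channel_agreement(b, a)
        assert ab.overall_pct == pytest.approx(ba.overall_pct)
        assert ab.seizure_pct == pytest.approx(50.0)
        assert ba.seizure_pct == pytest.approx(100.0)

    def test_unsure_excluded_pairwise(self):
        a = _frame(["seizure", "unsure", "non_seizure"])
        b = _frame(["seizure", "seizure", "missing"])
        bd = channel_agreement(a, b)
        assert bd.n_channels == 1

    def test_empty_join_rejected(self):
        with pytest.raises(ValueError):
            channel_agreement(_frame(["unsure"]), _frame(["seizure"]))


def _panel_annotations(bin_counts):
    """Build 3-reviewer annotations with exact k-of-3 seizure-vote counts."""
    rows = []
    ch = 0
    for k, n in enumerate(bin_counts):
        for _ in range(n):
            votes = ["seizure"] * k + ["non_seizure"] * (3 - k)
            for rev, lab in zip(("R1", "R2", "R3"), votes):
                rows.append({"record_id": f"r{ch}", "channel_index": 0,
                             "reviewer_id": rev, "label": lab})
            ch += 1
    return pd.DataFrame(rows)


class TestConsensusSummary:
    def test_published_vote_distribution(self):
        """Bin counts (1808, 382, 215, 1417) over a 3,874-channel responding
        denominator give the printed percentages 46.67 / 9.86 / 5.55 / 36.58
        (52 of the responding channels carry an unsure verdict and fall in
        no bin, which is why the four shares do not sum to 100)."""
        ann = _panel_annotations([1808, 382, 215, 1417])
        extra = []
        for i in range(52):
            for rev, lab in zip(("R1", "R2", "R3"),
                                ("seizure", "unsure", "non_seizure")):
                extra.append({"record_id": f"u{i}", "channel_index": 0,
                              "reviewer_id": rev, "label": lab})
        ann = pd.concat([ann, pd.DataFrame(extra)], ignore_index=True)
        summary = consensus_summary(ann, responded_denominator=True)
        assert summary.n_channels.tolist() == [1808, 382, 215, 1417]
        assert summary.pct.round(2).tolist() == [46.67, 9.86, 5.55, 36.58]
        assert summary.unanimous.tolist() == [True, False, False, True]
        # with the strict denominator the bins partition the decided set
        strict = consensus_summary(ann)
        assert strict.pct.sum() == pytest.approx(100.0)

    def test_unanimous_only_set(self):
        ann = _panel_annotations([6, 0, 0, 4])
        summary = consensus_summary(ann)
        assert summary[summary.unanimous].n_channels.sum() == 10
        assert summary[~summary.unanimous].n_channels.sum() == 0

    def test_single_split_vote(self):
        ann = _panel_annotations([0, 1, 0, 0])
        summary = consensus_summary(ann)
        assert summary.loc[summary.k == 1, "n_channels"].item() == 1

    def test_unsure_channels_excluded(self):
        ann = _panel_annotations([2, 0, 0, 2])
        extra = pd.DataFrame({
            "record_id": "rX", "channel_index": 0,
            "reviewer_id": ["R1", "R2", "R3"],
            "label": ["seizure", "unsure", "seizure"]})
        summary = consensus_summary(pd.concat([ann, extra]))
        assert summary.n_channels.sum() == 4

    def test_requires_three_reviewers(self):
        ann = _panel_annotations([1, 0, 0, 1])
        with pytest.raises(ValueError):
            consensus_summary(ann[ann.reviewer_id != "R3"])


class TestCalibration:
    def _votes(self, ks):
        return pd.DataFrame({"record_id": [f"r{i}" for i in range(len(ks))],
                             "channel_index": 0, "k": ks})

    def test_identity_calibration(self):
        ks = [0, 1, 2, 3] * 5
        votes = self._votes(ks)
        probs = votes.rename(columns={"k": "prob"}).assign(
            prob=np.array(ks) / 3)
        table = calibration(probs[["record_id", "channel_index", "prob"]],
                            votes)
        assert table.slope == pytest.approx(1.0)
        assert table.intercept == pytest.approx(0.0, abs=1e-12)
        assert table.r2 == pytest.approx(1.0)

    def test_constant_model_is_degenerate(self):
        ks = [0, 1, 2, 3] * 3
        votes = self._votes(ks)
        probs = votes.assign(prob=0.5)[["record_id", "channel_index", "prob"]]
        table = calibration(probs, votes)
        assert table.degenerate
        assert np.isnan(table.r2)

    def test_empty_bin_flagged(self):
        ks = [0, 3] * 4
        votes = self._votes(ks)
        probs = votes.assign(prob=np.array(ks) / 3)[
            ["record_id", "channel_index", "prob"]]
        table = calibration(probs, votes)
        assert set(table.empty_bins) == {1, 2}
        assert table.slope == pytest.approx(1.0)


class TestPRCurve:
    def test_perfect_separation(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        assert pr_curve(scores, [1, 1, 0, 0]).auprc == pytest.approx(1.0)

    def test_brute_force_equivalence_small_sets(self):
        """Average precision equals exhaustive threshold enumeration."""
        rng = np.random.default_rng(0)
        cases = [(np.array([.9, .8, .7, .6, .4, .2]),
                  np.array([1, 1, 0, 1, 0, 0]))]
        for _ in range(10):
            n = rng.integers(4, 21)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            cases.append((rng.uniform(0, 1, n), y))
        for scores, y in cases:
            expected = 0.0
            prev_recall = 0.0
            total_pos = y.sum()
            for t in sorted(np.unique(scores))[::-1]:
                pred = scores >= t
                tp = int((pred & (y == 1)).sum())
                recall = tp / total_pos
                precision = tp / pred.sum()
                expected += (recall - prev_recall) * precision
                prev_recall = recall
            assert pr_curve(scores, y).auprc == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pr_curve([0.1, 0.9], [1, 1])

    def test_chance_scorer_near_half(self):
        """Uniform scores on a balanced reference give AUPRC ~ 0.50."""
        rng = np.random.default_rng(1)
        y = np.array([1] * 5000 + [0] * 5000)
        auprc = pr_curve(rng.uniform(0, 1, 10000), y).auprc
        assert auprc == pytest.approx(0.5, abs=0.02)


class TestPairwiseRates:
    def _frames(self, ref_labels, test_labels):
        return (_frame(ref_labels), _frame(test_labels),
                {f"r{i}": f"p{i % 4}" for i in range(len(ref_labels))})

    def test_identical_is_perfect(self):
        ref, test, pmap = self._frames(["seizure", "non_seizure"] * 4,
                                       ["seizure", "non_seizure"] * 4)
        r = pairwise_rates(ref, test, pmap)
        assert r.sensitivity == 1.0
        assert r.false_positive_rate == 0.0

    def test_toy_two_by_two(self):
        ref_labels = ["seizure"] * 10 + ["non_seizure"] * 10
        test_labels = ["seizure"] * 9 + ["non_seizure"] + \
            ["seizure"] * 2 + ["non_seizure"] * 8
        ref, test, _ = self._frames(ref_labels, test_labels)
        pmap = {f"r{i}": "p0" for i in range(20)}  # one patient: pooled counts
        r = pairwise_rates(ref, test, pmap)
        assert r.sensitivity == pytest.approx(0.9)
        assert r.false_positive_rate == pytest.approx(0.2)
        # swapping roles changes the numbers
        r2 = pairwise_rates(test, ref, pmap)
        assert r2.sensitivity != r.sensitivity

    def test_no_reference_positives_rejected(self):
        ref, test, pmap = self._frames(["non_seizure"] * 4, ["seizure"] * 4)
        with pytest.raises(ValueError):
            pairwise_rates(ref, test, pmap)


class TestBCa:
    def test_constant_data_degenerate(self):
        ci = bca_interval([0.7] * 10, seed=0)
        assert ci.degenerate
        assert ci.lower == ci.upper == pytest.approx(0.7)

    def test_forced_z0_a_zero_equals_percentile(self):
        """With z0 = a = 0 the BCa endpoints are the percentile endpoints."""
        rng = np.random.default_rng(2)
        x = rng.standard_normal(80)
        ci = bca_interval(x, B=1000, seed=3, z0=0.0, a=0.0)
        boot = np.random.default_rng(3).integers(0, 80, size=(1000, 80))
        boot_means = x[boot].mean(axis=1)
        assert ci.lower == pytest.approx(np.quantile(boot_means, 0.025),
                                         abs=1e-9)
        assert ci.upper == pytest.approx(np.quantile(boot_means, 0.975),
                                         abs=1e-9)

    def test_symmetric_data_close_to_percentile(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(200)
        bca = bca_interval(x, B=2000, seed=5)
        pct = bca_interval(x, B=2000, seed=5, z0=0.0, a=0.0)
        assert abs(bca.lower - pct.lower) <= 0.015
        assert abs(bca.upper - pct.upper) <= 0.015

    def test_matches_scipy_reference(self):
        """Independent cross-check against scipy's BCa implementation."""
        rng = np.random.default_rng(6)
        x = rng.exponential(1.0, 60)
        ours = bca_interval(x, B=4000, seed=7)
        ref = stats.bootstrap((x,), np.mean, n_resamples=4000,
                              confidence_level=0.95, method="BCa",
                              rng=np.random.default_rng(8))
        assert ours.lower == pytest.approx(ref.confidence_interval.low,
                                           abs=0.03)
        assert ours.upper == pytest.approx(ref.confidence_interval.high,
                                           abs=0.03)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bca_interval([1.0], seed=0)
        with pytest.raises(ValueError):
            bca_interval([1.0, 2.0], B=10, seed=0)


def _rates(sens, fpr, sens_ci=None, fpr_ci=None):
    r = PairwiseRates("a", "b", sens, fpr, pd.DataFrame())
    if sens_ci:
        r.sensitivity_ci = BCaInterval(*sens_ci, sens, 0, 0)
    if fpr_ci:
        r.fpr_ci = BCaInterval(*fpr_ci, fpr, 0, 0)
    return r


class TestNoninferiority:
    def test_matching_point_is_noninferior(self):
        expert = _rates(0.9, 0.1, (0.85, 0.95), (0.05, 0.15))
        model = _rates(0.9, 0.1)
        verdict = noninferiority_check(model, [expert])
        assert verdict["noninferior"]

    def test_low_sensitivity_fails(self):
        experts = [_rates(0.9, 0.1, (0.85, 0.95), (0.05, 0.15)),
                   _rates(0.92, 0.12, (0.88, 0.96), (0.06, 0.18))]
        model = _rates(0.7, 0.1)
        verdict = noninferiority_check(model, experts)
        assert not verdict["sensitivity_ok"]
        assert not verdict["noninferior"]

    def test_missing_ci_rejected(self):
        with pytest.raises(ValueError):
            noninferiority_check(_rates(0.9, 0.1), [_rates(0.9, 0.1)])
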