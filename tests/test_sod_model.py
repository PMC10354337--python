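"""Onset regressor: initialization, training contract, checkpointing, leaks."""

import numpy as np
import pytest

from ictalflow.esc_model import BackboneSpec, TrainConfig, train_classifier
from ictalflow.nets import ConvTrunk
from ictalflow.sod_model import (build_sod, paired_fold_test, predict_onset,
                                 predict_onsets, run_ablation, train_sod)


@pytest.fixture(scope="module")
def classifier(easy_features):
    X, y, meta = easy_features
    folds = [(sorted(meta.patient_id.unique()), [])]
    cfg = TrainConfig(learning_rate=1e-2, n_epochs=10, batch_size=16, seed=0)
    return train_classifier(X, y, meta.patient_id, folds, cfg)[0]


@pytest.fixture(scope="module")
def sod_items(easy_cohort, easy_features):
    """Seizure-channel regression items from the shared cohort."""
    _, _, truths = easy_cohort
    X, _, meta = easy_features
    truth_map = {(t.record_id, t.channel_index): t for t in truths}
    items = []
    for i, row in enumerate(meta.itertuples()):
        t = truth_map[(row.record_id, row.channel_index)]
        if t.is_seizure:
            items.append({"x": X[i], "onset_s": t.onset_time_s,
                          "patient_id": row.patient_id,
                          "record_id": row.record_id,
                          "channel_index": row.channel_index,
                          "augmented": False})
    return items


class TestBuildSod:
    def test_task_pretrained_copies_backbone_bitwise(self, classifier):
        bundle = build_sod(classifier, "task_pretrained", seed=0)
        for k in ConvTrunk.BACKBONE_KEYS:
            assert np.array_equal(bundle.net.params[k],
                                  classifier.net.params[k])
        assert bundle.init_provenance == "task_pretrained"
        assert bundle.head == "dense_regression"

    def test_random_init_reproducible(self):
        spec = BackboneSpec()
        a = build_sod(spec, "random", seed=5)
        b = build_sod(spec, "random", seed=5)
        for k in a.net.params:
            assert np.array_equal(a.net.params[k], b.net.params[k])

    def test_untrained_output_is_finite_scalar(self):
        bundle = build_sod(BackboneSpec(), "random", seed=1)
        x = np.random.default_rng(0).uniform(0, 1, (32, 48, 1))
        val = predict_onset(bundle, x)
        assert np.isfinite(val)
        assert 0.0 <= val <= 90.0

    def test_generic_pretrained_differs_from_random(self):
        spec = BackboneSpec()
        g = build_sod(spec, "generic_pretrained", seed=2)
        r = build_sod(spec, "random", seed=2)
        assert not np.array_equal(g.net.params["conv1_W"],
                                  r.net.params["conv1_W"])

    def test_requires_classification_base(self):
        with pytest.raises(ValueError):
            build_sod(BackboneSpec(), "task_pretrained", seed=0)
        with pytest.raises(ValueError):
            build_sod(BackboneSpec(), "no_such_init", seed=0)


class TestPredictOnset:
    def test_head_mismatch_rejected(self, classifier):
        x = np.random.default_rng(0).uniform(0, 1, (32, 48, 1))
        with pytest.raises(ValueError):
            predict_onset(classifier, x)
        from ictalflow.esc_model import predict_channel
        reg = build_sod(BackboneSpec(), "random", seed=0)
        with pytest.raises(ValueError):
            predict_channel(reg, x)

    def test_deterministic_and_clipped(self):
        bundle = build_sod(BackboneSpec(), "random", seed=3)
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (5, 32, 48, 1))
        a = predict_onsets(bundle, X)
        b = predict_onsets(bundle, X)
        assert np.array_equal(a, b)
        assert np.all((a >= 0) & (a <= 90))


@pytest.fixture(scope="module")
def two_fold_run(sod_items, classifier):
    patients = sorted({it["patient_id"] for it in sod_items})
    half = len(patients) // 2
    folds = [(patients[:half], patients[half:]),
             (patients[half:], patients[:half])]
    cfg = TrainConfig(learning_rate=1e-2, n_epochs=4, batch_size=16, seed=0)
    results = train_sod(sod_items, folds, cfg, "task_pretrained", False,
                        classifier)
    return results, folds, cfg


class TestTrainSod:
    def test_one_result_per_fold_with_history(self, two_fold_run):
        results, folds, cfg = two_fold_run
        assert [r.fold_id for r in results] == [0, 1]
        for r in results:
            assert len(r.history["median_abs_err_s"]) == cfg.n_epochs
            assert r.init_provenance == "task_pretrained"

    def test_checkpoint_is_history_minimum(self, two_fold_run):
        """The selected epoch's metric equals the minimum of its history."""
        results, *_ = two_fold_run
        for r in results:
            hist = r.history["median_abs_err_s"]
            assert r.best_median_abs_err_s == min(hist)
            assert hist[r.selected_epoch] == min(hist)

    def test_returned_bundle_reproduces_best_epoch(self, two_fold_run,
                                                   sod_items):
        """Checkpointed weights reproduce the selected epoch's metric."""
        results, folds, _ = two_fold_run
        r = results[0]
        val = [it for it in sod_items
               if it["patient_id"] in set(folds[0][1])]
        X = np.stack([it["x"] for it in val])
        y = np.array([it["onset_s"] for it in val])
        preds = predict_onsets(r.bundle, X)
        assert np.median(np.abs(preds - y)) == pytest.approx(
            r.best_median_abs_err_s)

    def test_leak_guard(self, sod_items, classifier):
        """An augmented copy sourced from a validation patient aborts training."""
        patients = sorted({it["patient_id"] for it in sod_items})
        train_p, val_p = patients[:-1], patients[-1:]
        poisoned = [dict(it) for it in sod_items]
        bad = dict(poisoned[0])
        bad.update(augmented=True, patient_id=train_p[0],
                   source_patient_id=val_p[0], shift_s=5.0)
        poisoned.append(bad)
        cfg = TrainConfig(learning_rate=1e-2, n_epochs=1, seed=0)
        with pytest.raises(ValueError, match="leak"):
            train_sod(poisoned, [(train_p, val_p)], cfg, "random", True)

    def test_missing_onset_rejected(self, sod_items):
        broken = [dict(sod_items[0])]
        broken[0]["onset_s"] = None
        cfg = TrainConfig(learning_rate=1e-2, n_epochs=1, seed=0)
        with pytest.raises(ValueError, match="onset"):
            train_sod(broken, [([], [])], cfg, "random", False)


class TestAblation:
    def test_identical_arms_give_p_of_one(self):
        assert paired_fold_test([3.1, 2.9, 3.5], [3.1, 2.9, 3.5]) == 1.0

    def test_differing_arms_give_small_p(self):
        p = paired_fold_test([3.0, 3.1, 2.9, 3.2, 3.0],
                             [5.0, 5.2, 4.8, 5.1, 5.0])
        assert p < 0.05

    def test_table_has_arm_times_fold_rows(self, sod_items, classifier):
        patients = sorted({it["patient_id"] for it in sod_items})
        half = len(patients) // 2
        folds = [(patients[:half], patients[half:]),
                 (patients[half:], patients[:half])]
        cfg = TrainConfig(learning_rate=1e-2, n_epochs=2, batch_size=16,
                          seed=0)
        arms = {"a": {"init": "random", "use_augmented": False},
                "b": {"init": "task_pretrained", "use_augmented": False}}
        table, pvalues, results = run_ablation(sod_items, arms, folds, cfg,
                                               classifier)
        assert len(table) == len(arms) * len(folds)
        assert set(table.arm) == {"a", "b"}
        assert ("a", "b") in pvalues
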