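"""Seizure Onset Detection: fine-tuning a classifier into an onset regressor.

The regressor shares the classifier's convolutional backbone and evidence
projection; its head reads the positional expectation of the evidence
rises.  Training minimizes a Huber loss on normalized onsets with Adam;
models are checkpointed every epoch and the epoch with the lowest
validation median absolute error is selected.  Three weight
initializations are supported: ``task_pretrained`` (from a trained
classifier, with a deterministic orientation calibration of the
transferred evidence head), ``random``, and ``generic_pretrained`` (a
backbone pretrained on a synthetic texture-discrimination task).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .esc_model import (BackboneSpec, ModelBundle, TrainConfig,
                        build_backbone)
from .nets import (Adam, huber_loss_grad, orient_transferred_head,
                   pretrain_generic_backbone)

__all__ = [
    "SODTrainResult",
    "build_sod",
    "train_sod",
    "predict_onset",
    "predict_onsets",
    "run_ablation",
    "paired_fold_test",
]

INIT_STRATEGIES = ("task_pretrained", "random", "generic_pretrained")


@dataclass
class SODTrainResult:
    """One fold's fine-tuning outcome with its full metric history."""

    bundle: ModelBundle
    history: dict = field(default_factory=dict)
    selected_epoch: int = -1
    init_provenance: str = "random"
    augmented: bool = False
    fold_id: int = -1

    @property
    def best_median_abs_err_s(self) -> float:
        return self.history["median_abs_err_s"][self.selected_epoch]


def build_sod(base, init: str, *, seed: int = 0, gain=None,
              x_train=None, y_train=None, duration_s: float = 90.0) -> ModelBundle:
    """Build an onset regressor with the requested weight initialization.

    ``base`` is a trained classification :class:`ModelBundle` for
    ``task_pretrained`` (its backbone and evidence projection are copied
    bit-for-bit, then the evidence orientation is calibrated on the
    training items if given), or a :class:`BackboneSpec` otherwise.
    """
    if init not in INIT_STRATEGIES:
        raise ValueError(f"unknown init strategy {init!r}")
    rng = np.random.default_rng(seed)
    if init == "task_pretrained":
        if not isinstance(base, ModelBundle) or base.head != "sigmoid_binary":
            raise ValueError("task_pretrained requires a trained classification bundle")
        spec = base.backbone
        net = build_backbone(spec, "dense_regression", rng=rng, gain=gain)
        net.load_transferable(base.net.get_weights())
        if x_train is not None and y_train is not None:
            orient_transferred_head(base.net.get_weights(), net,
                                    np.asarray(x_train, dtype=float),
                                    np.asarray(y_train, dtype=float) / duration_s)
    else:
        spec = base if isinstance(base, BackboneSpec) else base.backbone
        net = build_backbone(spec, "dense_regression", rng=rng, gain=gain)
        if init == "generic_pretrained":
            generic = pretrain_generic_backbone(
                spec.input_hw, spec.channels, spec.conv_channels, seed=seed)
            net.load_transferable(generic.get_weights())
    return ModelBundle(backbone=spec, head="dense_regression",
                       init_provenance=init, fold_id=-1, net=net, seed=seed)


def predict_onset(bundle: ModelBundle, model_input,
                  duration_s: float = 90.0) -> float:
    """Predicted onset time in seconds, clipped to [0, duration]."""
    if bundle.head != "dense_regression":
        raise ValueError("predict_onset requires a regression head")
    img = model_input.image if hasattr(model_input, "image") else np.asarray(model_input)
    raw = float(bundle.net.forward(img[None])[0])
    return float(np.clip(raw * duration_s, 0.0, duration_s))


def predict_onsets(bundle: ModelBundle, inputs: np.ndarray,
                   duration_s: float = 90.0) -> np.ndarray:
    if bundle.head != "dense_regression":
        raise ValueError("predict_onsets requires a regression head")
    raw = bundle.net.forward(np.asarray(inputs, dtype=float))
    return np.clip(raw * duration_s, 0.0, duration_s)


def _onset_metrics(pred_s: np.ndarray, true_s: np.ndarray) -> dict:
    err = pred_s - true_s
    return {
        "median_abs_err_s": float(np.median(np.abs(err))),
        "mean_abs_err_s": float(np.mean(np.abs(err))),
        "rmse_s": float(np.sqrt(np.mean(err ** 2))),
    }


def _check_no_leak(train_items, val_patients) -> None:
    """An augmented item sourced from a validation patient must never train."""
    val = set(val_patients)
    for it in train_items:
        if it.get("augmented"):
            src = it.get("source_patient_id", it["patient_id"])
            if src in val:
                raise ValueError(
                    f"leak: augmented copy of {it['record_id']} (patient {src}) "
                    "from a validation patient found in the training set")


def train_sod(items, folds, config: TrainConfig, init: str,
              use_augmented: bool, base_classifier: ModelBundle | None = None,
              duration_s: float = 90.0, gain=None) -> list[SODTrainResult]:
    """Fine-tune one onset regressor per fold.

    ``items`` is a list of dicts with keys ``x`` (image tensor),
    ``onset_s``, ``patient_id``, ``record_id``, ``channel_index`` and the
    ``augmented`` flag produced by the augmentation stage.  For each fold,
    training uses train-patient items (originals plus, when
    ``use_augmented``, their augmented copies); validation uses original
    items of validation patients only.
    """
    for it in items:
        if it.get("onset_s") is None:
            raise ValueError("every onset-regression item needs a valid onset")
    results = []
    for fold_id, (train_p, val_p) in enumerate(folds):
        train_set = [it for it in items
                     if it["patient_id"] in set(train_p)
                     and (use_augmented or not it.get("augmented"))]
        val_set = [it for it in items
                   if it["patient_id"] in set(val_p) and not it.get("augmented")]
        _check_no_leak(train_set, val_p)
        if not train_set or not val_set:
            raise ValueError(f"fold {fold_id} has an empty train or validation set")
        Xtr = np.stack([it["x"] for it in train_set])
        ytr = np.array([it["onset_s"] for it in train_set]) / duration_s
        Xva = np.stack([it["x"] for it in val_set])
        yva = np.array([it["onset_s"] for it in val_set])

        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(7, fold_id)))
        seed_fold = int(rng.integers(1 << 31))
        if init == "task_pretrained":
            if base_classifier is None:
                raise ValueError("task_pretrained needs a base classifier bundle")
            bundle = build_sod(base_classifier, init, seed=seed_fold, gain=gain,
                               x_train=Xtr, y_train=ytr * duration_s,
                               duration_s=duration_s)
        else:
            spec = (base_classifier.backbone if base_classifier is not None
                    else BackboneSpec(input_hw=Xtr.shape[1:3],
                                      channels=Xtr.shape[3]))
            bundle = build_sod(spec, init, seed=seed_fold, gain=gain)
        net = bundle.net
        opt = Adam(net.params, lr=config.learning_rate)
        idx = np.arange(len(Xtr))
        history = {"train_loss": [], "median_abs_err_s": [],
                   "mean_abs_err_s": [], "rmse_s": []}
        best = (np.inf, net.get_weights(), -1)
        for epoch in range(config.n_epochs):
            rng.shuffle(idx)
            ep_loss = 0.0
            for start in range(0, len(idx), config.batch_size):
                b = idx[start:start + config.batch_size]
                out, cache = net.forward(Xtr[b], want_cache=True)
                loss, grad = huber_loss_grad(out, ytr[b])
                opt.step(net.params, net.backward(cache, grad))
                ep_loss += loss * len(b)
            history["train_loss"].append(ep_loss / len(idx))
            pred = np.clip(net.forward(Xva) * duration_s, 0.0, duration_s)
            m = _onset_metrics(pred, yva)
            for k, v in m.items():
                history[k].append(v)
            if m["median_abs_err_s"] < best[0]:
                best = (m["median_abs_err_s"], net.get_weights(), epoch)
        net.set_weights(best[1])
        bundle.fold_id = fold_id
        bundle.training_history = history
        results.append(SODTrainResult(
            bundle=bundle, history=history, selected_epoch=best[2],
            init_provenance=init, augmented=use_augmented, fold_id=fold_id))
    return results


def paired_fold_test(errors_a, errors_b) -> float:
    """Paired t-test p-value on per-fold errors (p = 1 for identical arms)."""
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired comparison needs equal-length fold errors")
    if np.allclose(a, b):
        return 1.0
    if a.size < 2:
        return float("nan")  # a single fold cannot support a paired test
    return float(stats.ttest_rel(a, b).pvalue)


def run_ablation(items, arms: dict, folds, config: TrainConfig,
                 base_classifier: ModelBundle | None = None,
                 duration_s: float = 90.0):
    """Run several (init x augmentation) arms over shared folds and seeds.

    ``arms`` maps an arm name to ``{"init": ..., "use_augmented": ...}``.
    Returns ``(table, pvalues, results)``: a per-(arm, fold) DataFrame of
    selected-epoch errors, paired t-test p-values for every arm pair, and
    the raw per-arm results.
    """
    if len(arms) < 1:
        raise ValueError("at least one arm required")
    results = {}
    rows = []
    for name, spec in arms.items():
        res = train_sod(items, folds, config, spec["init"],
                        spec["use_augmented"], base_classifier,
                        duration_s=duration_s)
        results[name] = res
        for r in res:
            rows.append({
                "arm": name,
                "init": spec["init"],
                "augmented": spec["use_augmented"],
                "fold_id": r.fold_id,
                "median_abs_err_s": r.best_median_abs_err_s,
                "selected_epoch": r.selected_epoch,
            })
    table = pd.DataFrame(rows)
    pvalues = {}
    for a, b in combinations(arms, 2):
        ea = [r.best_median_abs_err_s for r in results[a]]
        eb = [r.best_median_abs_err_s for r in results[b]]
        pvalues[(a, b)] = paired_fold_test(ea, eb)
    return table, pvalues, results
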