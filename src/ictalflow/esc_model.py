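"""Electrographic Seizure Classifier: training, prediction, operating points.

Per-channel seizure probabilities come from a small convolutional network
trained on spectrogram images with a class-weighted cross-entropy loss and
patient-wise five-fold cross-validation (folds partition patients, never
records, so no patient contributes to both sides of a fold).  Channel and
record classification use an operating point theta with the ``>= theta``
convention at both levels; a record's probability is the maximum over its
1-4 channel probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nets import Adam, EvidenceClassifier, OnsetRegressor, bce_loss_grad

__all__ = [
    "BackboneSpec",
    "TrainConfig",
    "OperatingPoint",
    "ModelBundle",
    "build_backbone",
    "patient_folds",
    "train_classifier",
    "predict_channel",
    "predict_proba",
    "classify_channel",
    "classify_record",
    "reviewer_record_label",
    "balanced_accuracy",
    "save_bundle",
    "load_bundle",
]

BACKBONE_FAMILIES = ("small_cnn", "resnet50_class")
HEADS = ("sigmoid_binary", "dense_regression")
INIT_PROVENANCES = ("random", "generic_pretrained", "task_pretrained")


@dataclass
class BackboneSpec:
    """Architecture description; ``small_cnn`` is the desk-scale default."""

    family: str = "small_cnn"
    input_hw: tuple = (32, 48)
    channels: int = 1
    conv_channels: tuple = (8, 16)

    def __post_init__(self):
        if self.family not in BACKBONE_FAMILIES:
            raise ValueError(f"unknown backbone family {self.family!r}")

    @property
    def n_params(self) -> int:
        return build_backbone(self, head="sigmoid_binary").n_params


@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the published protocol."""

    optimizer: str = "adam"
    learning_rate: float = 0.0001
    n_epochs: int = 400
    batch_size: int = 16
    n_folds: int = 5
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")
        if self.n_epochs <= 0 or self.batch_size <= 0 or self.n_folds < 2:
            raise ValueError("invalid training configuration")


@dataclass
class OperatingPoint:
    """Probability threshold; ``probability >= threshold`` means seizure."""

    threshold: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("operating point must lie strictly in (0, 1)")


@dataclass
class ModelBundle:
    """A trained network plus its provenance and training history."""

    backbone: BackboneSpec
    head: str
    init_provenance: str
    fold_id: int
    training_history: dict = field(default_factory=dict)
    net: object = None
    seed: int = 0

    def __post_init__(self):
        if self.head not in HEADS:
            raise ValueError(f"unknown head {self.head!r}")
        if self.init_provenance not in INIT_PROVENANCES:
            raise ValueError(f"unknown init provenance {self.init_provenance!r}")


def build_backbone(spec: BackboneSpec, head: str, rng=None, gain=None):
    """Instantiate a network for ``spec``; resnet50_class needs a GPU runtime."""
    if spec.family == "resnet50_class":
        raise NotImplementedError(
            "the resnet50_class backbone requires an external deep-learning "
            "runtime; use the small_cnn family")
    if head == "sigmoid_binary":
        return EvidenceClassifier(spec.input_hw, spec.channels,
                                  spec.conv_channels, rng=rng)
    if head == "dense_regression":
        kwargs = {} if gain is None else {"gain": gain}
        return OnsetRegressor(spec.input_hw, spec.channels,
                              spec.conv_channels, rng=rng, **kwargs)
    raise ValueError(f"unknown head {head!r}")


# ---------------------------------------------------------------------------
# cross-validation folds
# ---------------------------------------------------------------------------

def patient_folds(patient_ids, k: int = 5, seed: int = 0):
    """Partition patients into ``k`` folds: list of (train, validation) id lists."""
    unique = sorted(set(patient_ids))
    if k > len(unique):
        raise ValueError(f"cannot make {k} folds from {len(unique)} patients")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(unique))
    chunks = [list(c) for c in np.array_split(order, k)]
    folds = []
    for i in range(k):
        val = sorted(chunks[i])
        train = sorted(p for j, c in enumerate(chunks) if j != i for p in c)
        folds.append((train, val))
    return folds


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def balanced_accuracy(prob: np.ndarray, y: np.ndarray,
                      threshold: float = 0.5) -> float:
    """Mean of per-class recalls (sensitivity and specificity averaged)."""
    pos, neg = y == 1, y == 0
    if not pos.any() or not neg.any():
        raise ValueError("both classes required for balanced accuracy")
    return 0.5 * (np.mean(prob[pos] >= threshold)
                  + np.mean(prob[neg] < threshold))


def train_classifier(inputs: np.ndarray, labels: np.ndarray,
                     patient_of_item, folds, config: TrainConfig,
                     backbone: BackboneSpec | None = None) -> list[ModelBundle]:
    """Train one classifier per patient fold; returns a bundle per fold.

    ``inputs``: (N, H, W, C) spectrogram images; ``labels``: 0/1 seizure;
    ``patient_of_item``: patient id per item.  Class imbalance is handled by
    a class-weighted cross-entropy.  The checkpoint kept for each fold is the
    epoch with the lowest validation loss.
    """
    inputs = np.asarray(inputs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    patients = np.asarray(patient_of_item)
    backbone = backbone or BackboneSpec(input_hw=inputs.shape[1:3],
                                        channels=inputs.shape[3])
    bundles = []
    for fold_id, (train_p, val_p) in enumerate(folds):
        tr = np.isin(patients, train_p)
        va = np.isin(patients, val_p)
        ytr = labels[tr]
        if len(np.unique(ytr)) < 2:
            raise ValueError(f"training fold {fold_id} contains a single class")
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(fold_id,)))
        net = build_backbone(backbone, "sigmoid_binary", rng=rng)
        opt = Adam(net.params, lr=config.learning_rate)
        Xtr, Xva, yva = inputs[tr], inputs[va], labels[va]
        w = np.where(ytr == 1, 0.5 / max(ytr.mean(), 1e-9),
                     0.5 / max(1 - ytr.mean(), 1e-9))
        idx = np.arange(len(Xtr))
        history = {"train_loss": [], "val_loss": [], "val_balanced_accuracy": []}
        best = (np.inf, net.get_weights())
        for _ in range(config.n_epochs):
            rng.shuffle(idx)
            ep_loss = 0.0
            for start in range(0, len(idx), config.batch_size):
                b = idx[start:start + config.batch_size]
                prob, cache = net.forward(Xtr[b], want_cache=True)
                loss, grad = bce_loss_grad(prob, ytr[b], w[b])
                opt.step(net.params, net.backward(cache, grad))
                ep_loss += loss * len(b)
            history["train_loss"].append(ep_loss / len(idx))
            if va.any():
                pv = net.forward(Xva)
                vloss, _ = bce_loss_grad(pv, yva)
                history["val_loss"].append(float(vloss))
                try:
                    history["val_balanced_accuracy"].append(
                        float(balanced_accuracy(pv, yva)))
                except ValueError:
                    history["val_balanced_accuracy"].append(float("nan"))
                if vloss < best[0]:
                    best = (vloss, net.get_weights())
        if va.any():
            net.set_weights(best[1])
        bundles.append(ModelBundle(
            backbone=backbone, head="sigmoid_binary", init_provenance="random",
            fold_id=fold_id, training_history=history, net=net,
            seed=config.seed))
    return bundles


# ---------------------------------------------------------------------------
# prediction and classification rules
# ---------------------------------------------------------------------------

def _image_of(model_input) -> np.ndarray:
    return model_input.image if hasattr(model_input, "image") else np.asarray(model_input)


def predict_channel(bundle: ModelBundle, model_input) -> float:
    """Seizure probability in [0, 1] for one channel image."""
    if bundle.head != "sigmoid_binary":
        raise ValueError("predict_channel requires a classification head")
    return float(bundle.net.forward(_image_of(model_input)[None])[0])


def predict_proba(bundle: ModelBundle, inputs: np.ndarray) -> np.ndarray:
    """Vectorized seizure probabilities for a batch of channel images."""
    if bundle.head != "sigmoid_binary":
        raise ValueError("predict_proba requires a classification head")
    return bundle.net.forward(np.asarray(inputs, dtype=float))


def classify_channel(probability: float, op: OperatingPoint) -> str:
    if not 0.0 <= probability <= 1.0:
        raise ValueError("probability outside [0, 1]")
    return "seizure" if probability >= op.threshold else "non_seizure"


def classify_record(channel_probabilities, op: OperatingPoint):
    """Record rule: max channel probability, seizure iff max >= theta."""
    probs = list(channel_probabilities)
    if not 1 <= len(probs) <= 4:
        raise ValueError("a record carries 1-4 channel probabilities")
    record_probability = float(max(probs))
    return record_probability, classify_channel(record_probability, op)


def reviewer_record_label(channel_labels) -> str:
    """Any-channel rule for one reviewer's record verdict.

    Seizure if any channel is labelled seizure; unsure/missing channels are
    ignored by the any-rule; the record is missing only when every channel
    is missing.
    """
    labels = list(channel_labels)
    if not labels:
        raise ValueError("at least one channel annotation required")
    if any(l == "seizure" for l in labels):
        return "seizure"
    if all(l == "missing" for l in labels):
        return "missing"
    return "non_seizure"


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_bundle(bundle: ModelBundle, directory) -> None:
    """Write a bundle as a JSON manifest plus an .npz of weights."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "backbone": {
            "family": bundle.backbone.family,
            "input_hw": list(bundle.backbone.input_hw),
            "channels": bundle.backbone.channels,
            "conv_channels": list(bundle.backbone.conv_channels),
        },
        "head": bundle.head,
        "init_provenance": bundle.init_provenance,
        "fold_id": bundle.fold_id,
        "seed": bundle.seed,
        "training_history": bundle.training_history,
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
    np.savez(d / "weights.npz", **bundle.net.params)


def load_bundle(directory) -> ModelBundle:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    spec = BackboneSpec(
        family=manifest["backbone"]["family"],
        input_hw=tuple(manifest["backbone"]["input_hw"]),
        channels=manifest["backbone"]["channels"],
        conv_channels=tuple(manifest["backbone"]["conv_channels"]),
    )
    net = build_backbone(spec, manifest["head"])
    with np.load(d / "weights.npz") as z:
        net.set_weights({k: z[k] for k in z.files})
    return ModelBundle(
        backbone=spec, head=manifest["head"],
        init_provenance=manifest["init_provenance"],
        fold_id=manifest["fold_id"],
        training_history=manifest["training_history"],
        net=net, seed=manifest["seed"],
    )
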