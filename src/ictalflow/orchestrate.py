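"""Experiment configuration, seed streams, logging, and study recipes.

Two end-to-end studies tie the stages together:

* the *agreement study* — generate a cohort, simulate a three-reviewer
  panel, train the seizure classifier with patient-wise cross-validation,
  and emit agreement tables, calibration, precision-recall curves,
  pairwise rates with BCa intervals and a noninferiority verdict;
* the *SOD study* — fine-tune onset regressors over 2 (augmentation) x 3
  (initialization) arms on shared folds and emit the per-fold error table,
  metric curves, consensus-window errors, the trigger-time baseline and a
  signed-error histogram.

Every stochastic stage draws its seed deterministically from the single
global seed via named streams, so paired comparisons share randomness and
full runs are reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import augment as aug_mod
from . import onset_eval, rater_stats, sod_model, spectro
from . import esc_model as esc
from .synthdata import (CohortConfig, ReviewerProfile, annotations_to_frame,
                        default_reviewer_panel, generate_cohort,
                        simulate_reviewers)

__all__ = [
    "ExperimentConfig",
    "StageError",
    "seed_stream",
    "featurize_records",
    "run_agreement_study",
    "run_sod_study",
    "ordering_experiment",
]

log = logging.getLogger("ictalflow")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def seed_stream(global_seed: int, name: str) -> int:
    """Deterministic named child seed of the global seed (below 2**31)."""
    tag = zlib.crc32(name.encode())
    ss = np.random.SeedSequence(entropy=int(global_seed), spawn_key=(tag,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class ExperimentConfig:
    """Everything needed to rerun a study: cohorts, training, analysis knobs.

    Defaults keep the published protocol settings (operating points 0.5 /
    0.8 / 0.9, consensus windows 0.25-10 s, five folds, Adam at 1e-4);
    :meth:`desk_scale` returns the small, CPU-friendly configuration used
    by the bundled tests and examples.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    sod_cohort: CohortConfig = field(default_factory=lambda: CohortConfig(
        n_patients=50, records_per_patient=10, seizure_record_fraction=1.0))
    train: esc.TrainConfig = field(default_factory=esc.TrainConfig)
    sod_train: esc.TrainConfig = field(default_factory=esc.TrainConfig)
    augment: aug_mod.AugmentConfig = field(default_factory=aug_mod.AugmentConfig)
    reviewers: list = field(default_factory=default_reviewer_panel)
    operating_points: tuple = (0.5, 0.8, 0.9)
    record_operating_points: tuple = (0.8, 0.9)
    consensus_windows: tuple = onset_eval.DEFAULT_WINDOWS_S
    bootstrap_B: int = 2000
    alpha: float = 0.05
    input_hw: tuple = (32, 48)
    out_dir: str = "results"
    seed: int = 0

    @classmethod
    def desk_scale(cls, seed: int = 0, out_dir: str = "results") -> "ExperimentConfig":
        """CPU-friendly settings: small cohorts, short training runs."""
        return cls(
            cohort=CohortConfig(n_patients=10, records_per_patient=2,
                                seizure_record_fraction=0.5),
            sod_cohort=CohortConfig(n_patients=12, records_per_patient=2,
                                    seizure_record_fraction=1.0,
                                    ambiguity_low=0.0, ambiguity_high=0.0),
            train=esc.TrainConfig(learning_rate=1e-2, n_epochs=30,
                                  batch_size=16, n_folds=5),
            sod_train=esc.TrainConfig(learning_rate=1e-2, n_epochs=6,
                                      batch_size=16, n_folds=5),
            bootstrap_B=500,
            out_dir=out_dir,
            seed=seed,
        )

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def _cohort_from(d: dict) -> CohortConfig:
        d = dict(d)
        for key in ("lead_location_probs", "seizure_channel_count_probs"):
            d[key] = tuple(d[key])
        return CohortConfig(**d)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        d["cohort"] = cls._cohort_from(d["cohort"])
        d["sod_cohort"] = cls._cohort_from(d["sod_cohort"])
        d["train"] = esc.TrainConfig(**d["train"])
        d["sod_train"] = esc.TrainConfig(**d["sod_train"])
        d["augment"] = aug_mod.AugmentConfig(**d["augment"])
        d["reviewers"] = [ReviewerProfile(**r) for r in d["reviewers"]]
        for key in ("operating_points", "record_operating_points",
                    "consensus_windows", "input_hw"):
            d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

def featurize_records(records, input_hw=(32, 48), n_image_channels=1):
    """Spectrogram images for every channel of every record.

    Returns ``(X, meta)``: an (N, H, W, C) array and a DataFrame with
    record_id, channel_index, patient_id and lead_location per row.
    """
    images, meta = [], []
    for rec in records:
        for ch, x in enumerate(rec.channels):
            spec = spectro.compute_spectrogram(x, rec.sample_rate_hz)
            mi = spectro.to_model_input(spec, input_hw,
                                        n_image_channels=n_image_channels,
                                        record_id=rec.record_id,
                                        channel_index=ch)
            images.append(mi.image)
            meta.append({"record_id": rec.record_id, "channel_index": ch,
                         "patient_id": rec.patient_id,
                         "lead_location": rec.lead_location})
    return np.stack(images), pd.DataFrame(meta)


def _stage(name):
    """Decorator tagging a pipeline stage for error reporting."""
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as e:  # noqa: BLE001 - re-raised with stage name
                raise StageError(name, e) from e
        return wrapper
    return deco


# ---------------------------------------------------------------------------
# agreement study
# ---------------------------------------------------------------------------

def _model_label_frame(probs: pd.DataFrame, theta: float) -> pd.DataFrame:
    op = esc.OperatingPoint(theta)
    return probs.assign(
        label=[esc.classify_channel(p, op) for p in probs.prob])


def run_agreement_study(config: ExperimentConfig) -> dict:
    """Run the classification agreement study end to end; writes CSV/JSON.

    Returns the in-memory report dict; files land in ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort_cfg = replace(config.cohort, seed=seed_stream(config.seed, "cohort"))
    records, truths = _stage("cohort")(generate_cohort)(cohort_cfg)
    patient_of_record = {r.record_id: r.patient_id for r in records}
    lead_of_record = {r.record_id: r.lead_location for r in records}

    rng_rev = np.random.default_rng(seed_stream(config.seed, "reviewers"))
    annotations = _stage("reviewers")(simulate_reviewers)(
        truths, config.reviewers, rng_rev,
        duration_s=config.cohort.duration_s)
    ann_df = annotations_to_frame(annotations)
    ann_df["patient_id"] = ann_df.record_id.map(patient_of_record)
    ann_df["lead_location"] = ann_df.record_id.map(lead_of_record)

    X, meta = _stage("featurize")(featurize_records)(records, config.input_hw)
    truth_map = {(t.record_id, t.channel_index): t.is_seizure for t in truths}
    labels = np.array([truth_map[(r.record_id, r.channel_index)]
                       for r in meta.itertuples()], dtype=float)

    folds = esc.patient_folds(meta.patient_id, k=config.train.n_folds,
                              seed=seed_stream(config.seed, "folds"))
    train_cfg = replace(config.train, seed=seed_stream(config.seed, "train"))
    bundles = _stage("train_classifier")(esc.train_classifier)(
        X, labels, meta.patient_id, folds, train_cfg)

    # out-of-fold probabilities: each channel scored by the model whose
    # validation fold contains its patient
    probs = np.full(len(meta), np.nan)
    for bundle, (_, val_p) in zip(bundles, folds):
        mask = meta.patient_id.isin(val_p).to_numpy()
        if mask.any():
            probs[mask] = esc.predict_proba(bundle, X[mask])
    probs_df = meta[["record_id", "channel_index"]].assign(prob=probs)

    reviewer_ids = [p.reviewer_id for p in config.reviewers]
    rev_frames = {r: ann_df[ann_df.reviewer_id == r] for r in reviewer_ids}

    report: dict = {}

    # table-2-shaped coverage
    cov_rows = []
    for r in reviewer_ids:
        sub = rev_frames[r]
        rated = sub[sub.label.isin(("seizure", "non_seizure"))]
        cov_rows.append({"reviewer_id": r,
                         "n_records_annotated": rated.record_id.nunique(),
                         "n_channels_annotated": len(rated)})
    votes = rater_stats.consensus_votes(ann_df)
    coverage = pd.DataFrame(cov_rows)
    coverage_extra = {
        "n_records_all_three": int(
            votes.record_id.nunique()),
        "n_channels_all_three": int(len(votes)),
    }
    report["coverage"] = coverage

    # table-3-shaped: model vs unanimous-consensus channels, by stratum
    unanimous = votes[votes.k.isin((0, 3))].assign(
        label=lambda d: np.where(d.k == 3, "seizure", "non_seizure"))
    unanimous["lead_location"] = unanimous.record_id.map(lead_of_record)
    t3_rows = []
    for theta in config.operating_points[:2]:
        model_lab = _model_label_frame(probs_df, theta)
        for stratum in ("all", "MTL", "NEO", "MTL+NEO"):
            ref = unanimous if stratum == "all" else \
                unanimous[unanimous.lead_location == stratum]
            if ref.empty:
                continue
            bd = rater_stats.channel_agreement(ref, model_lab, stratum=stratum)
            t3_rows.append({"operating_point": theta, "stratum": stratum,
                            "n_channels": bd.n_channels,
                            "n_seizure": bd.n_seizure,
                            "n_nonseizure": bd.n_nonseizure,
                            "seizure_pct": bd.seizure_pct,
                            "nonseizure_pct": bd.nonseizure_pct,
                            "overall_pct": bd.overall_pct})
    report["unanimous_agreement"] = pd.DataFrame(t3_rows)

    # table-4-shaped: each reviewer as reference vs others and vs model
    t4_rows = []
    for ref_id in reviewer_ids:
        ref = rev_frames[ref_id]
        tests = [(other, rev_frames[other]) for other in reviewer_ids
                 if other != ref_id]
        tests += [(f"model@{theta}", _model_label_frame(probs_df, theta))
                  for theta in config.operating_points[:2]]
        for test_id, test_frame in tests:
            bd = rater_stats.channel_agreement(ref, test_frame)
            t4_rows.append({"reference": ref_id, "test": test_id,
                            "n_channels": bd.n_channels,
                            "n_seizure": bd.n_seizure,
                            "n_nonseizure": bd.n_nonseizure,
                            "overall_pct": bd.overall_pct,
                            "seizure_pct": bd.seizure_pct,
                            "nonseizure_pct": bd.nonseizure_pct})
    report["pairwise_agreement"] = pd.DataFrame(t4_rows)

    # table-5-shaped: record-level agreement (any-channel rule vs max-prob rule)
    rec_probs = probs_df.groupby("record_id").prob.apply(list)
    t5_rows = []
    for theta in config.record_operating_points:
        op = esc.OperatingPoint(theta)
        model_rec = pd.DataFrame({
            "record_id": rec_probs.index,
            "channel_index": 0,
            "label": [esc.classify_record(p, op)[1] for p in rec_probs],
        })
        for ref_id in reviewer_ids:
            rev_rec = rev_frames[ref_id].groupby("record_id").label.apply(
                lambda s: esc.reviewer_record_label(list(s))).reset_index()
            rev_rec["channel_index"] = 0
            bd = rater_stats.channel_agreement(rev_rec, model_rec)
            t5_rows.append({"reference": ref_id, "operating_point": theta,
                            "n_records": bd.n_channels,
                            "n_seizure": bd.n_seizure,
                            "n_nonseizure": bd.n_nonseizure,
                            "overall_pct": bd.overall_pct,
                            "seizure_pct": bd.seizure_pct,
                            "nonseizure_pct": bd.nonseizure_pct})
    report["record_agreement"] = pd.DataFrame(t5_rows)

    # calibration of model certainty against the k-of-3 vote
    calib = _stage("calibration")(rater_stats.calibration)(
        probs_df.dropna(subset=["prob"]), votes)
    report["calibration"] = calib

    # precision-recall against each reviewer and the unanimous subset
    pr_rows, auprc = [], {}
    targets = [(r, rev_frames[r]) for r in reviewer_ids]
    targets.append(("unanimous", unanimous))
    for name, frame in targets:
        ref = frame[frame.label.isin(("seizure", "non_seizure"))]
        j = ref.merge(probs_df, on=["record_id", "channel_index"]).dropna(
            subset=["prob"])
        if j.label.nunique() < 2:
            continue
        curve = rater_stats.pr_curve(j.prob, (j.label == "seizure").astype(int))
        auprc[name] = curve.auprc
        pr_rows.append(pd.DataFrame({
            "target": name,
            "threshold": np.concatenate([curve.thresholds, [np.nan]]),
            "precision": curve.precision,
            "recall": curve.recall}))
    report["pr_curves"] = pd.concat(pr_rows, ignore_index=True) if pr_rows \
        else pd.DataFrame(columns=["target", "threshold", "precision", "recall"])
    report["auprc"] = auprc

    # pairwise rates with BCa intervals + noninferiority
    bca_seed = seed_stream(config.seed, "bootstrap")
    theta_rates = config.record_operating_points[0]
    model_lab = _model_label_frame(probs_df, theta_rates)
    rate_rows, expert_pairs, model_pairs = [], [], []
    pair_id = 0
    for ref_id in reviewer_ids:
        for test_id in reviewer_ids:
            if test_id == ref_id:
                continue
            r = rater_stats.pairwise_rates(
                rev_frames[ref_id], rev_frames[test_id], patient_of_record,
                reference_id=ref_id, test_id=test_id)
            rater_stats.attach_cis(r, B=config.bootstrap_B, alpha=config.alpha,
                                   seed=bca_seed + pair_id)
            expert_pairs.append(r)
            pair_id += 2
        r = rater_stats.pairwise_rates(
            rev_frames[ref_id], model_lab, patient_of_record,
            reference_id=ref_id, test_id=f"model@{theta_rates}")
        rater_stats.attach_cis(r, B=config.bootstrap_B, alpha=config.alpha,
                               seed=bca_seed + pair_id)
        model_pairs.append(r)
        pair_id += 2
    for r in expert_pairs + model_pairs:
        rate_rows.append({
            "reference": r.reference_id, "test": r.test_id,
            "sensitivity": r.sensitivity,
            "sensitivity_lo": r.sensitivity_ci.lower,
            "sensitivity_hi": r.sensitivity_ci.upper,
            "fpr": r.false_positive_rate,
            "fpr_lo": r.fpr_ci.lower, "fpr_hi": r.fpr_ci.upper})
    report["pairwise_rates"] = pd.DataFrame(rate_rows)
    model_pooled = pd.concat([r.per_patient for r in model_pairs])
    pooled_model = rater_stats.PairwiseRates(
        reference_id="experts", test_id=f"model@{theta_rates}",
        sensitivity=float(model_pooled.sensitivity.dropna().mean()),
        false_positive_rate=float(
            model_pooled.false_positive_rate.dropna().mean()),
        per_patient=model_pooled)
    report["noninferiority"] = rater_stats.noninferiority_check(
        pooled_model, expert_pairs)

    # per-fold validation metrics of the classifier
    report["classifier_folds"] = pd.DataFrame([
        {"fold_id": b.fold_id,
         "val_balanced_accuracy": (b.training_history["val_balanced_accuracy"]
                                   [int(np.argmin(b.training_history["val_loss"]))]
                                   if b.training_history["val_loss"] else np.nan)}
        for b in bundles])

    _write_agreement_reports(report, coverage_extra, config, out)
    return report


def _write_agreement_reports(report, coverage_extra, config, out: Path) -> None:
    report["coverage"].to_csv(out / "coverage.csv", index=False)
    report["unanimous_agreement"].to_csv(out / "unanimous_agreement.csv",
                                         index=False)
    report["pairwise_agreement"].to_csv(out / "pairwise_agreement.csv",
                                        index=False)
    report["record_agreement"].to_csv(out / "record_agreement.csv", index=False)
    report["calibration"].bins.to_csv(out / "calibration.csv", index=False)
    report["pr_curves"].to_csv(out / "pr_curves.csv", index=False)
    report["pairwise_rates"].to_csv(out / "pairwise_rates.csv", index=False)
    report["classifier_folds"].to_csv(out / "classifier_folds.csv", index=False)
    (out / "calibration_fit.json").write_text(json.dumps({
        "slope": report["calibration"].slope,
        "intercept": report["calibration"].intercept,
        "r2": report["calibration"].r2,
        "degenerate": report["calibration"].degenerate,
    }, indent=2))
    (out / "auprc.json").write_text(json.dumps(report["auprc"], indent=2))
    (out / "noninferiority.json").write_text(
        json.dumps(report["noninferiority"], indent=2))
    (out / "manifest.json").write_text(json.dumps({
        "study": "agreement",
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "derived_seeds": {name: seed_stream(config.seed, name)
                          for name in ("cohort", "reviewers", "folds",
                                       "train", "bootstrap")},
        "coverage": coverage_extra,
        "files": sorted(p.name for p in out.iterdir()),
    }, indent=2))


# ---------------------------------------------------------------------------
# SOD study
# ---------------------------------------------------------------------------

SOD_ARMS = {
    "aug_task": {"init": "task_pretrained", "use_augmented": True},
    "orig_task": {"init": "task_pretrained", "use_augmented": False},
    "aug_random": {"init": "random", "use_augmented": True},
    "orig_random": {"init": "random", "use_augmented": False},
    "aug_generic": {"init": "generic_pretrained", "use_augmented": True},
    "orig_generic": {"init": "generic_pretrained", "use_augmented": False},
}


def _sod_items(records, truths, config: ExperimentConfig,
               fold_of_patient=None):
    """Featurized seizure-channel items for onset regression."""
    lookup = {r.record_id: r for r in records}
    channels = []
    for t in truths:
        if not t.is_seizure:
            continue
        rec = lookup[t.record_id]
        channels.append({
            "record_id": t.record_id, "channel_index": t.channel_index,
            "patient_id": rec.patient_id,
            "samples": rec.channels[t.channel_index],
            "onset_s": t.onset_time_s,
            "fold_id": (fold_of_patient or {}).get(rec.patient_id, -1),
        })
    aug_cfg = replace(config.augment,
                      seed=seed_stream(config.seed, "augmentation"))
    items, provenance = aug_mod.augment_dataset(
        channels, aug_cfg, config.sod_cohort.sample_rate_hz,
        config.sod_cohort.duration_s)
    for it in items:
        spec = spectro.compute_spectrogram(
            it["samples"], config.sod_cohort.sample_rate_hz)
        it["x"] = spectro.to_model_input(
            spec, config.input_hw, record_id=it["record_id"],
            channel_index=it["channel_index"]).image
        del it["samples"]
    return items, provenance


def _train_base_classifier(config: ExperimentConfig) -> esc.ModelBundle:
    """Train the classifier whose weights seed task-pretrained arms."""
    cls_cfg = replace(config.cohort,
                      seed=seed_stream(config.seed, "cls_cohort"))
    records, truths = generate_cohort(cls_cfg)
    X, meta = featurize_records(records, config.input_hw)
    truth_map = {(t.record_id, t.channel_index): t.is_seizure for t in truths}
    labels = np.array([truth_map[(r.record_id, r.channel_index)]
                       for r in meta.itertuples()], dtype=float)
    folds = [(sorted(meta.patient_id.unique()), [])]
    train_cfg = replace(config.train,
                        seed=seed_stream(config.seed, "cls_train"))
    return esc.train_classifier(X, labels, meta.patient_id, folds,
                                train_cfg)[0]


def run_sod_study(config: ExperimentConfig, arms: dict | None = None) -> dict:
    """Run the onset-detection ablation study end to end; writes CSV/JSON."""
    arms = arms if arms is not None else SOD_ARMS
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sod_cfg = replace(config.sod_cohort,
                      seed=seed_stream(config.seed, "sod_cohort"))
    records, truths = _stage("sod_cohort")(generate_cohort)(sod_cfg)
    patients = sorted({r.patient_id for r in records})
    folds = esc.patient_folds(patients, k=config.sod_train.n_folds,
                              seed=seed_stream(config.seed, "sod_folds"))
    fold_of_patient = {p: i for i, (_, val) in enumerate(folds) for p in val}
    items, provenance = _stage("sod_items")(_sod_items)(
        records, truths, config, fold_of_patient)

    base = _stage("base_classifier")(_train_base_classifier)(config)

    sod_cfg_train = replace(config.sod_train,
                            seed=seed_stream(config.seed, "sod_train"))
    table, pvalues, results = _stage("ablation")(sod_model.run_ablation)(
        items, arms, folds, sod_cfg_train, base,
        duration_s=config.sod_cohort.duration_s)

    # per-epoch metric curves
    curve_rows = []
    for arm, res in results.items():
        for r in res:
            for epoch in range(len(r.history["median_abs_err_s"])):
                curve_rows.append({
                    "arm": arm, "fold_id": r.fold_id, "epoch": epoch,
                    "median_abs_err_s": r.history["median_abs_err_s"][epoch],
                    "mean_abs_err_s": r.history["mean_abs_err_s"][epoch],
                    "rmse_s": r.history["rmse_s"][epoch]})
    curves = pd.DataFrame(curve_rows)

    # out-of-fold predictions of the augmented task-pretrained arm
    best_arm = "aug_task" if "aug_task" in results else next(iter(results))
    originals = [it for it in items if not it.get("augmented")]
    pred_rows = []
    for r in results[best_arm]:
        _, val_p = folds[r.fold_id]
        val_items = [it for it in originals if it["patient_id"] in set(val_p)]
        if not val_items:
            continue
        Xv = np.stack([it["x"] for it in val_items])
        preds = sod_model.predict_onsets(r.bundle, Xv,
                                         config.sod_cohort.duration_s)
        for it, p in zip(val_items, preds):
            pred_rows.append({"record_id": it["record_id"],
                              "channel_index": it["channel_index"],
                              "true_onset_s": it["onset_s"],
                              "predicted_onset_s": float(p)})
    predictions = pd.DataFrame(pred_rows)

    # reviewer onsets on the same channels -> consensus-window evaluation
    rng_rev = np.random.default_rng(seed_stream(config.seed, "sod_reviewers"))
    annotations = simulate_reviewers(truths, config.reviewers, rng_rev,
                                     duration_s=config.sod_cohort.duration_s)
    ann_df = annotations_to_frame(annotations)
    cw_rows = []
    for w in config.consensus_windows:
        subset = onset_eval.consensus_subset(ann_df, w)
        j = subset.channels.merge(predictions, on=["record_id", "channel_index"])
        row = {"window_s": w, "n_channels": subset.n, "n_evaluated": len(j)}
        if len(j):
            summ = onset_eval.onset_errors(j.predicted_onset_s,
                                           j.reference_onset_s)
            row.update(median_abs_err_s=summ.median_abs_err_s,
                       mean_abs_err_s=summ.mean_abs_err_s,
                       rmse_s=summ.rmse_s)
        cw_rows.append(row)
    consensus_windows = pd.DataFrame(cw_rows)

    # trigger-time baseline on the evaluated channels
    baseline = {}
    hist = pd.DataFrame()
    if len(predictions):
        base_preds = onset_eval.trigger_baseline(
            records, predictions[["record_id", "channel_index"]])
        j = predictions.merge(base_preds, on=["record_id", "channel_index"])
        model_summ = onset_eval.onset_errors(j.predicted_onset_s_x,
                                             j.true_onset_s)
        base_summ = onset_eval.onset_errors(j.predicted_onset_s_y,
                                            j.true_onset_s)
        baseline = {
            "model_median_abs_err_s": model_summ.median_abs_err_s,
            "baseline_median_abs_err_s": base_summ.median_abs_err_s,
            "model_beats_baseline":
                bool(model_summ.median_abs_err_s < base_summ.median_abs_err_s),
            "n_positive_errors": model_summ.n_positive,
            "n_negative_errors": model_summ.n_negative,
        }
        hist = onset_eval.signed_error_histogram(model_summ)

    means = table.groupby("arm").median_abs_err_s.mean()
    ordering = {}
    for name, a, b in (
            ("augmented_le_original_task", "aug_task", "orig_task"),
            ("augmented_le_original_random", "aug_random", "orig_random"),
            ("task_le_random_augmented", "aug_task", "aug_random")):
        if a in means.index and b in means.index:
            ordering[name] = bool(means[a] <= means[b])

    table.to_csv(out / "sod_fold_errors.csv", index=False)
    curves.to_csv(out / "sod_metric_curves.csv", index=False)
    consensus_windows.to_csv(out / "consensus_window_errors.csv", index=False)
    predictions.to_csv(out / "sod_predictions.csv", index=False)
    provenance.to_csv(out / "augmentation_provenance.csv", index=False)
    hist.to_csv(out / "signed_error_histogram.csv", index=False)
    (out / "sod_pvalues.json").write_text(json.dumps(
        {f"{a}__vs__{b}": p for (a, b), p in pvalues.items()}, indent=2))
    (out / "sod_baseline.json").write_text(json.dumps(baseline, indent=2))
    (out / "sod_ordering.json").write_text(json.dumps(ordering, indent=2))
    (out / "manifest.json").write_text(json.dumps({
        "study": "sod",
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "derived_seeds": {name: seed_stream(config.seed, name)
                          for name in ("sod_cohort", "sod_folds", "cls_cohort",
                                       "cls_train", "sod_train",
                                       "augmentation", "sod_reviewers")},
        "files": sorted(p.name for p in out.iterdir()),
    }, indent=2))
    return {"table": table, "pvalues": pvalues, "curves": curves,
            "consensus_windows": consensus_windows, "baseline": baseline,
            "ordering": ordering, "predictions": predictions,
            "results": results}


# ---------------------------------------------------------------------------
# desk-scale ordering experiment (biased train / uniform validation)
# ---------------------------------------------------------------------------

def ordering_experiment(seed: int, *, n_train_patients: int = 12,
                        n_val_patients: int = 6,
                        records_per_patient: int = 2,
                        epochs: int = 6, clf_epochs: int = 40,
                        learning_rate: float = 1e-2,
                        input_hw=(32, 48)) -> dict:
    """One seed of the augmentation / initialization ordering experiment.

    Training patients carry the long-episode onset bias (~N(30 s, 3 s));
    validation patients carry uniform onsets over most of the record, so a
    model that merely memorizes the training onset distribution fails on
    validation.  Three arms share data and fold: original-only with random
    init, augmented with random init, augmented with task-pretrained init.
    Also evaluates the trigger-time baseline on the validation channels.
    """
    duration = 90.0
    cfg = ExperimentConfig(
        sod_cohort=CohortConfig(
            n_patients=n_train_patients,
            records_per_patient=records_per_patient,
            seizure_record_fraction=1.0, onset_center_s=30.0,
            onset_spread_s=3.0, ambiguity_low=0.0, ambiguity_high=0.0),
        cohort=CohortConfig(
            n_patients=10, records_per_patient=2,
            seizure_record_fraction=0.5, ambiguity_low=0.0,
            ambiguity_high=0.0),
        train=esc.TrainConfig(learning_rate=learning_rate,
                              n_epochs=clf_epochs, batch_size=16),
        sod_train=esc.TrainConfig(learning_rate=learning_rate,
                                  n_epochs=epochs, batch_size=16),
        input_hw=tuple(input_hw),
        seed=seed,
    )
    train_cfg = replace(cfg.sod_cohort,
                        seed=seed_stream(seed, "ordering_train_cohort"))
    val_cfg = CohortConfig(
        n_patients=n_val_patients, records_per_patient=records_per_patient,
        seizure_record_fraction=1.0, onset_center_s=45.0, onset_spread_s=35.0,
        onset_distribution="uniform", ambiguity_low=0.0, ambiguity_high=0.0,
        seed=seed_stream(seed, "ordering_val_cohort"))
    rec_t, tru_t = generate_cohort(train_cfg)
    rec_v, tru_v = generate_cohort(val_cfg)
    # disambiguate patient ids across the two cohorts
    for r in rec_v:
        r.patient_id = "V" + r.patient_id
    items_t, _ = _sod_items(rec_t, tru_t, cfg)
    cfg_v = dataclasses.replace(cfg, sod_cohort=val_cfg)
    items_v, _ = _sod_items(rec_v, tru_v, cfg_v)
    items_v = [it for it in items_v if not it.get("augmented")]
    items = items_t + items_v
    train_p = sorted({it["patient_id"] for it in items_t})
    val_p = sorted({it["patient_id"] for it in items_v})
    folds = [(train_p, val_p)]

    base = _train_base_classifier(cfg)
    sod_cfg = replace(cfg.sod_train, seed=seed_stream(seed, "ordering_train"))
    arms = {
        "orig_random": {"init": "random", "use_augmented": False},
        "aug_random": {"init": "random", "use_augmented": True},
        "aug_task": {"init": "task_pretrained", "use_augmented": True},
    }
    table, _, results = sod_model.run_ablation(items, arms, folds, sod_cfg,
                                               base, duration_s=duration)
    errors = {arm: float(table[table.arm == arm].median_abs_err_s.iloc[0])
              for arm in arms}

    # trigger baseline vs the augmented task-pretrained model
    val_items = items_v
    Xv = np.stack([it["x"] for it in val_items])
    preds = sod_model.predict_onsets(results["aug_task"][0].bundle, Xv,
                                     duration)
    truth = np.array([it["onset_s"] for it in val_items])
    frame = pd.DataFrame([{"record_id": it["record_id"],
                           "channel_index": it["channel_index"]}
                          for it in val_items])
    base_pred = onset_eval.trigger_baseline(rec_v, frame)
    model_summ = onset_eval.onset_errors(preds, truth)
    base_summ = onset_eval.onset_errors(base_pred.predicted_onset_s, truth)
    errors.update(
        baseline_median_abs_err_s=base_summ.median_abs_err_s,
        model_median_abs_err_s=model_summ.median_abs_err_s,
    )
    return errors
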