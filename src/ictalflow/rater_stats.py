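"""Reviewer-vs-reviewer and model-vs-reviewer statistics.

Agreement breakdowns, 3-reviewer consensus summaries, certainty
calibration against the k-of-3 reviewer vote, precision-recall curves,
pairwise sensitivity / false-positive rates with patient-clustered BCa
bootstrap confidence intervals, and a noninferiority verdict.  Channels
with unsure or missing labels are excluded pairwise (or, for consensus
analyses, whenever any of the three reviewers declined a call).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, precision_recall_curve

__all__ = [
    "AgreementBreakdown",
    "CalibrationTable",
    "PairwiseRates",
    "PRCurve",
    "BCaInterval",
    "channel_agreement",
    "consensus_summary",
    "consensus_votes",
    "calibration",
    "attach_cis",
    "pr_curve",
    "pairwise_rates",
    "bca_interval",
    "noninferiority_check",
]

_VALID = ("seizure", "non_seizure")


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class AgreementBreakdown:
    n_channels: int
    overall_pct: float
    seizure_pct: float
    nonseizure_pct: float
    n_seizure: int
    n_nonseizure: int
    stratum: str = "all"


@dataclass
class CalibrationTable:
    bins: pd.DataFrame          # k, n_channels, reviewer_probability, model_mean, model_sd
    slope: float
    intercept: float
    r2: float
    degenerate: bool = False
    empty_bins: tuple = ()


@dataclass
class BCaInterval:
    lower: float
    upper: float
    point: float
    z0: float
    a: float
    degenerate: bool = False


@dataclass
class PairwiseRates:
    reference_id: str
    test_id: str
    sensitivity: float
    false_positive_rate: float
    per_patient: pd.DataFrame   # patient_id, sensitivity, false_positive_rate
    sensitivity_ci: BCaInterval | None = None
    fpr_ci: BCaInterval | None = None


@dataclass
class PRCurve:
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auprc: float


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------

def _join(labels_a: pd.DataFrame, labels_b: pd.DataFrame) -> pd.DataFrame:
    key = ["record_id", "channel_index"]
    a = labels_a[key + ["label"]].rename(columns={"label": "label_a"})
    b = labels_b[key + ["label"]].rename(columns={"label": "label_b"})
    j = a.merge(b, on=key)
    return j[j.label_a.isin(_VALID) & j.label_b.isin(_VALID)]


def channel_agreement(labels_a: pd.DataFrame, labels_b: pd.DataFrame,
                      stratum: str = "all") -> AgreementBreakdown:
    """Percent agreement of ``b`` with reference ``a`` on jointly-rated channels.

    ``seizure_pct`` restricts to channels the reference called seizure;
    ``nonseizure_pct`` to reference non-seizure channels.  Overall agreement
    is symmetric in the pair; the per-class breakdowns are
    reference-dependent.
    """
    j = _join(labels_a, labels_b)
    if j.empty:
        raise ValueError("no jointly annotated channels after exclusions")
    agree = j.label_a == j.label_b
    sz = j.label_a == "seizure"
    return AgreementBreakdown(
        n_channels=len(j),
        overall_pct=100.0 * agree.mean(),
        seizure_pct=100.0 * agree[sz].mean() if sz.any() else float("nan"),
        nonseizure_pct=100.0 * agree[~sz].mean() if (~sz).any() else float("nan"),
        n_seizure=int(sz.sum()),
        n_nonseizure=int((~sz).sum()),
        stratum=stratum,
    )


def consensus_summary(annotations: pd.DataFrame,
                      responded_denominator: bool = False) -> pd.DataFrame:
    """k-of-3 seizure-vote bins over channels fully rated by all 3 reviewers.

    ``annotations`` holds one row per (record_id, channel_index,
    reviewer_id) with a ``label`` column.  Channels with any unsure or
    missing verdict, or rated by fewer than all three reviewers, are
    excluded from the bins, which therefore partition the fully-decided
    channel set.  With ``responded_denominator`` the percentages are taken
    over every channel where all three reviewers responded (unsure
    included) — the convention some reports print, in which the bin
    percentages need not sum to 100.  Returns a DataFrame with rows
    k = 0..3 and columns ``n_channels``, ``pct`` and ``unanimous``.
    """
    reviewers = annotations.reviewer_id.unique()
    if len(reviewers) != 3:
        raise ValueError(f"consensus summary requires exactly 3 reviewers, "
                         f"got {len(reviewers)}")
    valid = annotations[annotations.label.isin(_VALID)]
    counts = valid.groupby(["record_id", "channel_index"]).agg(
        n=("label", "size"), k=("label", lambda s: (s == "seizure").sum()))
    full = counts[counts.n == 3]
    if responded_denominator:
        responded = annotations[annotations.label != "missing"]
        total = int((responded.groupby(["record_id", "channel_index"])
                     .size() == 3).sum())
    else:
        total = len(full)
    if total == 0:
        raise ValueError("no channels fully annotated by all three reviewers")
    rows = []
    for k in range(4):
        n = int((full.k == k).sum())
        rows.append({"k": k, "n_channels": n, "pct": 100.0 * n / total,
                     "unanimous": k in (0, 3)})
    return pd.DataFrame(rows)


def consensus_votes(annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-channel k-of-3 seizure votes (fully-annotated channels only)."""
    valid = annotations[annotations.label.isin(_VALID)]
    counts = valid.groupby(["record_id", "channel_index"]).agg(
        n=("label", "size"), k=("label", lambda s: (s == "seizure").sum()))
    return counts[counts.n == 3].reset_index()[["record_id", "channel_index", "k"]]


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibration(model_probs: pd.DataFrame, votes: pd.DataFrame) -> CalibrationTable:
    """Model certainty vs combined reviewer certainty (k/3).

    ``model_probs``: (record_id, channel_index, prob); ``votes``:
    (record_id, channel_index, k).  Fits an ordinary least-squares line to
    the per-bin mean model probabilities against k/3 and reports the
    squared Pearson correlation of those bin means.
    """
    j = model_probs.merge(votes, on=["record_id", "channel_index"])
    if j.empty:
        raise ValueError("no channels with both model scores and full votes")
    rows, empty = [], []
    for k in range(4):
        sub = j[j.k == k]
        if sub.empty:
            empty.append(k)
            rows.append({"k": k, "n_channels": 0, "reviewer_probability": k / 3,
                         "model_mean": np.nan, "model_sd": np.nan})
        else:
            rows.append({"k": k, "n_channels": len(sub),
                         "reviewer_probability": k / 3,
                         "model_mean": float(sub.prob.mean()),
                         "model_sd": float(sub.prob.std(ddof=0))})
    bins = pd.DataFrame(rows)
    fit = bins.dropna(subset=["model_mean"])
    x = fit.reviewer_probability.to_numpy()
    y = fit.model_mean.to_numpy()
    degenerate = False
    if len(x) < 2 or np.ptp(y) < 1e-12 or np.ptp(x) < 1e-12:
        slope, intercept, r2 = 0.0, float(np.mean(y)), float("nan")
        degenerate = True
    else:
        slope, intercept = np.polyfit(x, y, 1)
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    return CalibrationTable(bins=bins, slope=float(slope),
                            intercept=float(intercept), r2=r2,
                            degenerate=degenerate, empty_bins=tuple(empty))


# ---------------------------------------------------------------------------
# precision-recall
# ---------------------------------------------------------------------------

def pr_curve(scores, binary_reference) -> PRCurve:
    """Precision-recall curve with step-wise (average-precision) AUPRC."""
    y = np.asarray(binary_reference, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required in the reference")
    precision, recall, thresholds = precision_recall_curve(y, s)
    auprc = float(average_precision_score(y, s))
    return PRCurve(thresholds=thresholds, precision=precision,
                   recall=recall, auprc=auprc)


# ---------------------------------------------------------------------------
# pairwise rates
# ---------------------------------------------------------------------------

def pairwise_rates(reference: pd.DataFrame, test: pd.DataFrame,
                   patient_of_record: dict, reference_id: str = "ref",
                   test_id: str = "test") -> PairwiseRates:
    """Sensitivity and false-positive rate of ``test`` against ``reference``.

    Channels with unsure/missing labels on either side are excluded.
    Per-patient rates are computed on each patient's channels; a patient
    without reference positives (negatives) does not contribute to the
    sensitivity (FPR) mean.  The pooled point estimates reported are the
    means of the defined per-patient rates (the bootstrap resampling unit
    is the patient).
    """
    j = _join(reference, test)
    if j.empty:
        raise ValueError("no jointly annotated channels")
    j = j.assign(patient_id=j.record_id.map(patient_of_record))
    if j.patient_id.isna().any():
        raise ValueError("records missing a patient mapping")
    ref_pos = j.label_a == "seizure"
    if not ref_pos.any():
        raise ValueError("reference contains no seizure channels; "
                         "sensitivity undefined")
    rows = []
    for pid, sub in j.groupby("patient_id"):
        pos = sub.label_a == "seizure"
        sens = (sub.label_b[pos] == "seizure").mean() if pos.any() else np.nan
        fpr = (sub.label_b[~pos] == "seizure").mean() if (~pos).any() else np.nan
        rows.append({"patient_id": pid, "sensitivity": sens,
                     "false_positive_rate": fpr})
    per_patient = pd.DataFrame(rows)
    return PairwiseRates(
        reference_id=reference_id, test_id=test_id,
        sensitivity=float(per_patient.sensitivity.dropna().mean()),
        false_positive_rate=float(per_patient.false_positive_rate.dropna().mean()),
        per_patient=per_patient,
    )


# ---------------------------------------------------------------------------
# BCa bootstrap
# ---------------------------------------------------------------------------

def bca_interval(values, statistic=np.mean, B: int = 2000, alpha: float = 0.05,
                 seed: int = 0, z0: float | None = None,
                 a: float | None = None) -> BCaInterval:
    """Efron's bias-corrected and accelerated bootstrap interval.

    ``values`` are the per-patient statistics (the resampling unit).  The
    bias term z0 comes from the fraction of bootstrap statistics below the
    point estimate; the acceleration a from the jackknife skewness
    ``a = sum(d^3) / (6 * sum(d^2)^1.5)`` with ``d = mean(jack) - jack``.
    ``z0``/``a`` may be forced (e.g. to 0, reducing the interval to the
    percentile bootstrap).  Deterministic under ``seed``.
    """
    x = np.asarray(pd.Series(values).dropna(), dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values for a bootstrap interval")
    if B < 200:
        raise ValueError("use at least 200 bootstrap resamples")
    point = float(statistic(x))
    if np.ptp(x) < 1e-15:
        return BCaInterval(point, point, point, 0.0, 0.0, degenerate=True)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    boot = np.apply_along_axis(statistic, 1, x[idx]) \
        if statistic is not np.mean else x[idx].mean(axis=1)
    if z0 is None:
        prop = np.clip(np.mean(boot < point), 1.0 / (B + 1), B / (B + 1))
        z0 = float(stats.norm.ppf(prop))
    if a is None:
        jack = np.array([statistic(np.delete(x, i)) for i in range(n)])
        d = jack.mean() - jack
        denom = np.sum(d ** 2) ** 1.5
        a = float(np.sum(d ** 3) / (6.0 * denom)) if denom > 0 else 0.0
    out = []
    for z_alpha in (stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)):
        zadj = z0 + (z0 + z_alpha) / (1.0 - a * (z0 + z_alpha))
        p = float(stats.norm.cdf(zadj))
        out.append(float(np.quantile(boot, p)))
    return BCaInterval(out[0], out[1], point, float(z0), float(a))


def attach_cis(rates: PairwiseRates, B: int = 2000, alpha: float = 0.05,
               seed: int = 0) -> PairwiseRates:
    """Attach patient-clustered BCa intervals to a rate pair."""
    rates.sensitivity_ci = bca_interval(
        rates.per_patient.sensitivity, B=B, alpha=alpha, seed=seed)
    rates.fpr_ci = bca_interval(
        rates.per_patient.false_positive_rate, B=B, alpha=alpha, seed=seed + 1)
    return rates


# ---------------------------------------------------------------------------
# noninferiority
# ---------------------------------------------------------------------------

def noninferiority_check(model_rates: PairwiseRates,
                         reviewer_pair_rates: list) -> dict:
    """Model-vs-expert noninferiority on (sensitivity, FPR).

    The model is noninferior when its mean sensitivity is at least the
    smallest lower CI bound among expert pairs AND its mean FPR is at most
    the largest upper CI bound among expert pairs.  This is one concrete
    reading of "within the expert pairs' confidence band"; the bounds used
    are reported alongside the verdict.
    """
    if not reviewer_pair_rates:
        raise ValueError("need at least one expert pair")
    for r in reviewer_pair_rates:
        if r.sensitivity_ci is None or r.fpr_ci is None:
            raise ValueError("expert pair rates must carry BCa intervals")
    sens_floor = min(r.sensitivity_ci.lower for r in reviewer_pair_rates)
    fpr_ceiling = max(r.fpr_ci.upper for r in reviewer_pair_rates)
    sens_ok = model_rates.sensitivity >= sens_floor
    fpr_ok = model_rates.false_positive_rate <= fpr_ceiling
    return {
        "sensitivity_ok": bool(sens_ok),
        "fpr_ok": bool(fpr_ok),
        "noninferior": bool(sens_ok and fpr_ok),
        "sensitivity_floor": float(sens_floor),
        "fpr_ceiling": float(fpr_ceiling),
        "model_sensitivity": float(model_rates.sensitivity),
        "model_fpr": float(model_rates.false_positive_rate),
    }
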