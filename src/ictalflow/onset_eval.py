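"""Evaluation of onset predictions against (possibly disagreeing) reviewers.

Error metrics over predicted-minus-reference onsets, consensus-window
channel subsets (channels where the three reviewer onsets fall within a
given spread), the trigger-time baseline (the device-detected episode
start used as a trivial onset prediction), and a signed-error histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OnsetErrorSummary",
    "ConsensusWindowSubset",
    "onset_errors",
    "consensus_subset",
    "trigger_baseline",
    "signed_error_histogram",
]

DEFAULT_WINDOWS_S = (0.25, 1.5, 3.0, 5.0, 10.0)


@dataclass
class OnsetErrorSummary:
    n: int
    median_abs_err_s: float
    mean_abs_err_s: float
    rmse_s: float
    signed_errors: np.ndarray
    n_positive: int   # prediction later than reference
    n_negative: int


@dataclass
class ConsensusWindowSubset:
    window_s: float
    channels: pd.DataFrame  # record_id, channel_index, reference_onset_s, spread_s

    @property
    def n(self) -> int:
        return len(self.channels)


def onset_errors(predictions_s, references_s) -> OnsetErrorSummary:
    """Metrics over prediction - reference, joined positionally."""
    pred = np.asarray(predictions_s, dtype=float)
    ref = np.asarray(references_s, dtype=float)
    if pred.shape != ref.shape or pred.size == 0:
        raise ValueError("predictions and references must align and be non-empty")
    err = pred - ref
    return OnsetErrorSummary(
        n=err.size,
        median_abs_err_s=float(np.median(np.abs(err))),
        mean_abs_err_s=float(np.mean(np.abs(err))),
        rmse_s=float(np.sqrt(np.mean(err ** 2))),
        signed_errors=err,
        n_positive=int((err > 0).sum()),
        n_negative=int((err < 0).sum()),
    )


def consensus_subset(annotations: pd.DataFrame,
                     window_s: float) -> ConsensusWindowSubset:
    """Channels whose three reviewer onsets all fall within ``window_s``.

    ``annotations`` holds (record_id, channel_index, reviewer_id, label,
    onset_time_s, onset_before_record_start).  A channel qualifies only if
    all three reviewers labelled it seizure with a valid in-record onset;
    any before-record-start flag excludes it.  The reference onset is the
    arithmetic mean of the three annotations.
    """
    sz = annotations[(annotations.label == "seizure")]
    rows = []
    for (rid, ch), sub in sz.groupby(["record_id", "channel_index"]):
        if len(sub) != 3 or len(sub.reviewer_id.unique()) != 3:
            continue
        if sub.onset_before_record_start.any() or sub.onset_time_s.isna().any():
            continue
        onsets = sub.onset_time_s.to_numpy(dtype=float)
        spread = float(onsets.max() - onsets.min())
        if spread <= window_s:
            rows.append({"record_id": rid, "channel_index": ch,
                         "reference_onset_s": float(onsets.mean()),
                         "spread_s": spread})
    channels = pd.DataFrame(
        rows, columns=["record_id", "channel_index", "reference_onset_s",
                       "spread_s"])
    return ConsensusWindowSubset(window_s=window_s, channels=channels)


def trigger_baseline(records, seizure_channels: pd.DataFrame) -> pd.DataFrame:
    """Trivial baseline: predict the device trigger time for every channel.

    ``seizure_channels`` needs (record_id, channel_index); the returned
    frame adds ``predicted_onset_s`` taken from each record's trigger.
    """
    triggers = {}
    for rec in records:
        if rec.trigger_time_s is None:
            raise ValueError(f"record {rec.record_id} has no trigger time")
        triggers[rec.record_id] = float(rec.trigger_time_s)
    missing = set(seizure_channels.record_id) - set(triggers)
    if missing:
        raise ValueError(f"records without trigger times: {sorted(missing)[:3]}")
    out = seizure_channels.copy()
    out["predicted_onset_s"] = out.record_id.map(triggers)
    return out


def signed_error_histogram(summary: OnsetErrorSummary,
                           bin_width_s: float = 2.0) -> pd.DataFrame:
    """Histogram of signed errors as (bin_left, bin_right, count) rows."""
    err = summary.signed_errors
    lo = np.floor(err.min() / bin_width_s) * bin_width_s
    hi = np.ceil(err.max() / bin_width_s) * bin_width_s
    edges = np.arange(lo, hi + bin_width_s, bin_width_s)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width_s])
    counts, _ = np.histogram(err, bins=edges)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts})
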