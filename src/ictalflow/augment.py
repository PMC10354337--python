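"""Onset-preserving right-shift augmentation of seizure channels.

A channel is shifted right by deleting samples from the end and duplicating
an equal stretch of (pre-onset) activity at the beginning, so the onset
label moves by exactly the shift.  Shifts are drawn once per 5-s bin of the
allowable range, capped, and snapped to whole samples.  Left shifts are
never produced: deleting the start and duplicating the tail could paste
ictal activity after the seizure end and fabricate a second seizure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AugmentedChannel",
    "AugmentConfig",
    "time_shift_channel",
    "sample_shifts",
    "augment_dataset",
]


@dataclass
class AugmentedChannel:
    """One right-shifted copy of a seizure channel."""

    record_id: str
    channel_index: int
    shift_s: float
    samples: np.ndarray
    new_onset_s: float

    def __post_init__(self):
        if self.shift_s <= 0:
            raise ValueError("augmented channels carry strictly positive shifts")


@dataclass
class AugmentConfig:
    """Augmentation knobs.

    ``range_step_s`` is the width of each shift-sampling bin (one uniform
    draw per bin); ``margin_s`` keeps the shifted onset at least this many
    seconds from the record end so some post-onset activity survives the
    tail deletion; ``copies_per_channel`` caps the number of augmented
    copies (a cap of 6 yields the ~6-7x dataset expansion typical for
    onsets near 30 s in a 90-s record).
    """

    range_step_s: float = 5.0
    margin_s: float = 5.0
    copies_per_channel: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.range_step_s <= 0:
            raise ValueError("range_step_s must be positive")
        if self.margin_s < 0:
            raise ValueError("margin_s must be non-negative")
        if self.copies_per_channel is not None and self.copies_per_channel < 1:
            raise ValueError("copies_per_channel cap must be >= 1")


def time_shift_channel(samples: np.ndarray, onset_s: float, shift_s: float,
                       sample_rate_hz: float, *, record_id: str = "",
                       channel_index: int = -1) -> AugmentedChannel:
    """Shift one channel right by ``shift_s`` (snapped to whole samples).

    ``output[k + s] = input[k]`` for the surviving samples and the first
    ``s`` samples are duplicated from the start of the input; the onset
    label becomes ``onset_s + s/fs``.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    duration_s = n / sample_rate_hz
    if shift_s <= 0:
        raise ValueError("left or zero shifts are not allowed "
                         "(shift must be strictly positive)")
    s = int(round(shift_s * sample_rate_hz))
    if s <= 0:
        raise ValueError("shift smaller than one sample")
    if s >= n:
        raise ValueError("shift exceeds the record length")
    snapped_shift = s / sample_rate_hz
    new_onset = onset_s + snapped_shift
    if new_onset >= duration_s:
        raise ValueError("shift pushes the onset past the record end")
    shifted = np.concatenate([x[:s], x[:n - s]])
    return AugmentedChannel(record_id=record_id, channel_index=channel_index,
                            shift_s=snapped_shift, samples=shifted,
                            new_onset_s=new_onset)


def sample_shifts(onset_s: float, duration_s: float, config: AugmentConfig,
                  rng: np.random.Generator) -> list[float]:
    """Draw one uniform shift per ``range_step_s`` bin of the allowable range.

    The allowable total shift is ``duration_s - onset_s - margin_s``; bins
    are [0, step), [step, 2*step), ... up to that bound (the last bin may be
    partial).  Non-positive draws are skipped; at most
    ``copies_per_channel`` shifts are kept (a random subset, preserving
    range diversity).
    """
    if not 0 <= onset_s < duration_s:
        raise ValueError("onset outside the record")
    max_shift = duration_s - onset_s - config.margin_s
    if max_shift <= 0:
        return []
    n_bins = int(np.floor(max_shift / config.range_step_s))
    shifts = []
    for k in range(n_bins):
        lo = k * config.range_step_s
        draw = float(rng.uniform(lo, lo + config.range_step_s))
        if draw > 0:
            shifts.append(draw)
    cap = config.copies_per_channel
    if cap is not None and len(shifts) > cap:
        keep = rng.choice(len(shifts), size=cap, replace=False)
        shifts = [shifts[i] for i in sorted(keep)]
    return shifts


def augment_dataset(channels, config: AugmentConfig, sample_rate_hz: float,
                    duration_s: float):
    """Augment a list of seizure channels; originals are retained.

    ``channels``: iterable of dicts with keys ``record_id``,
    ``channel_index``, ``samples``, ``onset_s`` and optionally ``fold_id``
    and ``patient_id``.  Augmentation is applied after fold assignment, so
    every augmented item inherits its source's fold.  Returns
    ``(items, provenance)`` where ``items`` contains the originals followed
    by the augmented copies (each a dict with an added ``augmented`` flag,
    ``shift_s`` and ``source_aug_id``), and ``provenance`` is a DataFrame
    of the augmented copies.
    """
    rng = np.random.default_rng(config.seed)
    items, prov = [], []
    aug_id = 0
    for ch in channels:
        onset = ch.get("onset_s")
        if onset is None or (isinstance(onset, float) and np.isnan(onset)):
            warnings.warn(
                f"channel {ch.get('record_id')}/{ch.get('channel_index')} "
                "has no onset; skipped")
            continue
        base = dict(ch)
        base.update(augmented=False, shift_s=0.0)
        items.append(base)
        for shift in sample_shifts(onset, duration_s, config, rng):
            aug = time_shift_channel(
                ch["samples"], onset, shift, sample_rate_hz,
                record_id=ch["record_id"], channel_index=ch["channel_index"])
            item = dict(ch)
            item.update(samples=aug.samples, onset_s=aug.new_onset_s,
                        augmented=True, shift_s=aug.shift_s,
                        source_aug_id=aug_id)
            items.append(item)
            prov.append({
                "aug_id": aug_id,
                "source_record_id": ch["record_id"],
                "channel_index": ch["channel_index"],
                "shift_s": aug.shift_s,
                "new_onset_s": aug.new_onset_s,
                "fold_id": ch.get("fold_id", -1),
            })
            aug_id += 1
    provenance = pd.DataFrame(
        prov, columns=["aug_id", "source_record_id", "channel_index",
                       "shift_s", "new_onset_s", "fold_id"])
    return items, provenance
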