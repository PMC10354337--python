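"""Synthetic multi-patient iEEG cohorts with ground truth and simulated expert reviewers.

Emulates the structure of "long episode" records stored by a responsive
neurostimulation device: 90-s, 4-channel records sampled at 250 Hz, with the
device trigger placed roughly 30 s after seizure onset (60 s of pre-trigger
activity in a 90-s record).  Ground-truth seizure channels carry one of three
ictal morphologies; a panel of imperfect reviewers produces per-channel
seizure / non-seizure / unsure labels and 0.1-s-resolution onset annotations.

Everything is deterministic under a fixed seed: cohort generation derives one
child random stream per record from the cohort seed, and the reviewer
simulator consumes a single caller-supplied generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "IEEGRecord",
    "ChannelTruth",
    "ReviewerProfile",
    "ChannelAnnotation",
    "CohortConfig",
    "generate_record",
    "generate_cohort",
    "simulate_reviewers",
    "write_edf",
    "read_edf",
    "write_cohort_h5",
    "read_cohort_h5",
    "annotations_to_csv",
    "annotations_from_csv",
    "annotations_to_frame",
    "truths_to_csv",
    "truths_from_csv",
]

DEVICE_MODELS = ("RNS-300M", "RNS-320")
RECORD_TYPES = ("long_episode", "scheduled")
LEAD_LOCATIONS = ("MTL", "NEO", "MTL+NEO")
LABELS = ("seizure", "non_seizure", "unsure", "missing")

#: seconds between seizure onset and the device trigger for long-episode
#: records (the device stores 60 s pre-trigger / 30 s post-trigger, and a
#: long episode is declared ~30 s after detection begins).
TRIGGER_DELAY_S = 30.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class IEEGRecord:
    """One stored iEEG record: up to four channels of raw samples."""

    record_id: str
    patient_id: str
    device_model: str = "RNS-320"
    record_type: str = "long_episode"
    sample_rate_hz: float = 250.0
    duration_s: float = 90.0
    trigger_time_s: float = 60.0
    channels: list = field(default_factory=list)
    lead_location: str = "MTL"

    def __post_init__(self):
        if self.device_model not in DEVICE_MODELS:
            raise ValueError(f"unknown device model {self.device_model!r}")
        if self.record_type not in RECORD_TYPES:
            raise ValueError(f"unknown record type {self.record_type!r}")
        if not 0 <= self.trigger_time_s <= self.duration_s:
            raise ValueError("trigger_time_s outside the record")
        n = len(self.channels)
        if not 1 <= n <= 4:
            raise ValueError(f"records carry 1-4 channels, got {n}")
        expected = round(self.duration_s * self.sample_rate_hz)
        for i, ch in enumerate(self.channels):
            if len(ch) != expected:
                raise ValueError(
                    f"channel {i} has {len(ch)} samples, expected {expected}"
                )

    @property
    def n_samples(self) -> int:
        return round(self.duration_s * self.sample_rate_hz)


@dataclass
class ChannelTruth:
    """Ground truth for one channel, including the latent reviewer difficulty."""

    record_id: str
    channel_index: int
    is_seizure: bool
    onset_time_s: float | None = None
    ambiguity: float = 0.0

    def __post_init__(self):
        if self.is_seizure != (self.onset_time_s is not None):
            raise ValueError("onset_time_s must be present iff is_seizure")
        if not 0.0 <= self.ambiguity <= 1.0:
            raise ValueError("ambiguity must lie in [0, 1]")


@dataclass
class ReviewerProfile:
    """Behavioural parameters of one simulated expert reviewer.

    ``sensitivity``/``specificity`` act on unambiguous channels; latent
    channel ambiguity pulls the labelling toward a fair coin.  ``unsure_rate``
    and ``missing_rate`` model channels the reviewer declines to call.
    """

    reviewer_id: str
    sensitivity: float = 0.95
    specificity: float = 0.95
    unsure_rate: float = 0.01
    onset_jitter_sd_s: float = 1.0
    onset_bias_s: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.sensitivity <= 1.0:
            raise ValueError("sensitivity must lie in (0, 1]")
        if not 0.0 < self.specificity <= 1.0:
            raise ValueError("specificity must lie in (0, 1]")
        if not 0.0 <= self.unsure_rate < 1.0:
            raise ValueError("unsure_rate must lie in [0, 1)")
        if self.onset_jitter_sd_s < 0:
            raise ValueError("onset_jitter_sd_s must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class ChannelAnnotation:
    """One reviewer's verdict for one channel."""

    reviewer_id: str
    record_id: str
    channel_index: int
    label: str
    onset_time_s: float | None = None
    onset_before_record_start: bool = False

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.label != "seizure" and (
            self.onset_time_s is not None or self.onset_before_record_start
        ):
            raise ValueError("onset fields are only valid on seizure labels")
        if self.onset_time_s is not None:
            if not 0.0 <= self.onset_time_s <= 90.0 + 1e-9:
                # duration is not carried on the annotation; 90 s is the
                # fixed record length of this study design
                raise ValueError("onset_time_s outside the record")
            if abs(self.onset_time_s * 10 - round(self.onset_time_s * 10)) > 1e-6:
                raise ValueError("onset_time_s must be on a 0.1-s grid")


@dataclass
class CohortConfig:
    """Study-condition knobs for cohort generation.

    Defaults mirror the validation-study design: 100 patients contributing
    10 long-episode records each, ~35% of records containing an
    electrographic seizure, onsets centred 30 s after record start.
    """

    n_patients: int = 100
    records_per_patient: int = 10
    seizure_record_fraction: float = 0.35
    onset_center_s: float = 30.0
    onset_spread_s: float = 3.0
    onset_distribution: str = "normal"  # or "uniform" over [center-spread, center+spread]
    n_channels: int = 4
    duration_s: float = 90.0
    sample_rate_hz: float = 250.0
    ambiguity_low: float = 0.0
    ambiguity_high: float = 0.5
    lead_location_probs: tuple = (0.36, 0.29, 0.35)  # MTL, NEO, MTL+NEO
    seizure_channel_count_probs: tuple = (0.45, 0.30, 0.15, 0.10)  # 1..4 channels
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0 or self.records_per_patient <= 0:
            raise ValueError("patient and record counts must be positive")
        if not 0.0 <= self.seizure_record_fraction <= 1.0:
            raise ValueError("seizure_record_fraction must lie in [0, 1]")
        if not 1 <= self.n_channels <= 4:
            raise ValueError("n_channels must lie in 1..4")
        if not 0.0 <= self.ambiguity_low <= self.ambiguity_high <= 1.0:
            raise ValueError("ambiguity bounds must satisfy 0 <= low <= high <= 1")
        if self.onset_distribution not in ("normal", "uniform"):
            raise ValueError("onset_distribution must be 'normal' or 'uniform'")


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _background(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-shaped noise (unit RMS) with sparse interictal spikes."""
    white = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    # flat below 1 Hz, 1/f power above: amplitude ~ f^-0.5
    shape = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    x = np.fft.irfft(np.fft.rfft(white) * shape, n)
    x /= np.std(x)
    # sparse interictal spikes: brief biphasic transients
    duration = n / fs
    n_spikes = rng.poisson(0.08 * duration)
    t_axis = np.arange(n) / fs
    for _ in range(n_spikes):
        t0 = rng.uniform(0.5, duration - 0.5)
        amp = rng.uniform(2.0, 3.0) * rng.choice([-1.0, 1.0])
        width = rng.uniform(0.03, 0.06)
        d = t_axis - t0
        x += amp * d / width * np.exp(0.5 - 0.5 * (d / width) ** 2)
    return x


def _ramp(t_rel: np.ndarray, rise_s: float = 4.0) -> np.ndarray:
    """Amplitude envelope rising from ~0 to 1 over ``rise_s`` seconds."""
    return np.clip(t_rel / rise_s, 0.0, 1.0)


def _spike_wavelet(phase: np.ndarray) -> np.ndarray:
    """Sharp periodic spike shape for rhythmic ictal spiking (period 2*pi)."""
    # narrow gaussian bump per cycle plus a slower after-wave
    wrapped = np.mod(phase, 2 * np.pi) - np.pi
    spike = np.exp(-0.5 * (wrapped / 0.35) ** 2)
    wave = -0.45 * np.sin(phase)
    return spike + wave


def _seizure_waveform(
    n: int, fs: float, onset_s: float, morphology: str, rng: np.random.Generator
) -> np.ndarray:
    """Additive ictal activity beginning at ``onset_s`` and lasting to record end.

    All morphologies reach >= 3x the unit background RMS within ~4 s of onset
    and persist, so a window-RMS oracle can separate seizure from background.
    """
    t = np.arange(n) / fs
    rel = t - onset_s
    active = rel >= 0
    out = np.zeros(n)
    env = _ramp(rel) * (1.0 + 0.1 * np.sin(2 * np.pi * 0.11 * rel + rng.uniform(0, 2 * np.pi)))
    if morphology == "lvfa":
        # low-voltage fast activity: fast rhythm sweeping down while growing
        f0 = rng.uniform(22.0, 30.0)
        f1 = rng.uniform(10.0, 14.0)
        dur = max(t[-1] - onset_s, 1e-6)
        freq = f0 + (f1 - f0) * np.clip(rel / dur, 0, 1)
        phase = 2 * np.pi * np.cumsum(np.where(active, freq, 0.0)) / fs
        out[active] = (6.0 * env * np.sin(phase))[active]
    elif morphology == "hypersync":
        # hypersynchronous rhythmic spiking, 2-5 Hz
        f = rng.uniform(2.0, 5.0)
        phase = 2 * np.pi * f * np.where(active, rel, 0.0)
        out[active] = (9.0 * env * _spike_wavelet(phase))[active]
    elif morphology == "spikewave":
        # evolving spike-wave complexes: ~3 Hz slowing toward ~2 Hz
        f0 = rng.uniform(2.8, 3.6)
        dur = max(t[-1] - onset_s, 1e-6)
        freq = f0 * (1.0 - 0.3 * np.clip(rel / dur, 0, 1))
        phase = 2 * np.pi * np.cumsum(np.where(active, freq, 0.0)) / fs
        out[active] = (8.0 * env * (_spike_wavelet(phase) - 0.3 * np.sin(0.5 * phase)))[active]
    else:
        raise ValueError(f"unknown morphology {morphology!r}")
    return out


#: morphology palette per lead location (mesiotemporal onsets lean
#: hypersynchronous/low-voltage-fast; neocortical onsets more heterogeneous)
_MORPHOLOGIES = {
    "MTL": ("hypersync", "lvfa"),
    "NEO": ("lvfa", "spikewave"),
    "MTL+NEO": ("hypersync", "lvfa", "spikewave"),
}


def generate_record(
    config: CohortConfig,
    patient_id: str,
    truth_spec: Mapping[int, float],
    rng: np.random.Generator,
    *,
    record_id: str | None = None,
    lead_location: str = "MTL",
    device_model: str = "RNS-320",
) -> tuple[IEEGRecord, list[ChannelTruth]]:
    """Generate one record plus per-channel ground truth.

    ``truth_spec`` maps seizure channel indices to onset times (seconds);
    unlisted channels are non-seizure.
    """
    n = round(config.duration_s * config.sample_rate_hz)
    if not 1 <= config.n_channels <= 4:
        raise ValueError("n_channels outside 1-4")
    for ch, onset in truth_spec.items():
        if not 0 <= ch < config.n_channels:
            raise ValueError(f"seizure channel index {ch} out of range")
        if not 0.0 <= onset < config.duration_s:
            raise ValueError(f"onset {onset} beyond record duration")
    rid = record_id or f"{patient_id}_r{rng.integers(1 << 30):08d}"
    channels, truths = [], []
    for ch in range(config.n_channels):
        x = _background(n, config.sample_rate_hz, rng)
        if ch in truth_spec:
            onset = float(truth_spec[ch])
            morph = rng.choice(_MORPHOLOGIES[lead_location])
            x = x + _seizure_waveform(n, config.sample_rate_hz, onset, morph, rng)
            truths.append(
                ChannelTruth(
                    rid, ch, True, onset,
                    ambiguity=float(rng.uniform(config.ambiguity_low, config.ambiguity_high)),
                )
            )
        else:
            truths.append(
                ChannelTruth(
                    rid, ch, False, None,
                    ambiguity=float(rng.uniform(config.ambiguity_low, config.ambiguity_high)),
                )
            )
        channels.append(x)
    if truth_spec:
        trigger = float(np.clip(min(truth_spec.values()) + TRIGGER_DELAY_S, 0.0, config.duration_s))
    else:
        trigger = float(np.clip(config.onset_center_s + TRIGGER_DELAY_S, 0.0, config.duration_s))
    record = IEEGRecord(
        record_id=rid,
        patient_id=patient_id,
        device_model=device_model,
        record_type="long_episode",
        sample_rate_hz=config.sample_rate_hz,
        duration_s=config.duration_s,
        trigger_time_s=trigger,
        channels=channels,
        lead_location=lead_location,
    )
    return record, truths


def _draw_onset(config: CohortConfig, rng: np.random.Generator) -> float:
    lo, hi = 2.0, config.duration_s - 10.0
    if config.onset_distribution == "normal":
        onset = rng.normal(config.onset_center_s, config.onset_spread_s)
    else:
        onset = rng.uniform(
            config.onset_center_s - config.onset_spread_s,
            config.onset_center_s + config.onset_spread_s,
        )
    return float(np.clip(onset, lo, hi))


def generate_cohort(config: CohortConfig) -> tuple[list[IEEGRecord], list[ChannelTruth]]:
    """Generate ``n_patients * records_per_patient`` records with ground truth.

    One child random stream is derived per record (in a fixed order) from the
    cohort seed, so the cohort is reproducible record-by-record.
    """
    master = np.random.SeedSequence(config.seed)
    meta_rng = np.random.default_rng(master.spawn(1)[0])
    records: list[IEEGRecord] = []
    truths: list[ChannelTruth] = []
    # stratified seizure assignment: the seizure-record share matches the
    # configured fraction exactly (up to rounding) at any cohort size
    n_records = config.n_patients * config.records_per_patient
    n_seizure = round(config.seizure_record_fraction * n_records)
    flags = np.zeros(n_records, dtype=bool)
    flags[:n_seizure] = True
    meta_rng.shuffle(flags)
    for p in range(config.n_patients):
        patient_id = f"P{p:03d}"
        lead = meta_rng.choice(LEAD_LOCATIONS, p=config.lead_location_probs)
        device = DEVICE_MODELS[p % 2]
        for r in range(config.records_per_patient):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(1 + p, r))
            )
            rid = f"P{p:03d}_R{r:02d}"
            truth_spec: dict[int, float] = {}
            if flags[p * config.records_per_patient + r]:
                k = 1 + rng.choice(4, p=config.seizure_channel_count_probs)
                k = min(k, config.n_channels)
                base = _draw_onset(config, rng)
                for ch in sorted(rng.choice(config.n_channels, size=k, replace=False)):
                    onset = float(
                        np.clip(base + rng.uniform(-1.0, 1.0), 0.0, config.duration_s - 5.0)
                    )
                    truth_spec[int(ch)] = round(onset, 2)
            rec, tr = generate_record(
                config, patient_id, truth_spec, rng,
                record_id=rid, lead_location=str(lead), device_model=device,
            )
            records.append(rec)
            truths.extend(tr)
    return records, truths


# ---------------------------------------------------------------------------
# reviewer simulation
# ---------------------------------------------------------------------------

def simulate_reviewers(
    truths: Sequence[ChannelTruth],
    profiles: Sequence[ReviewerProfile],
    rng: np.random.Generator,
    *,
    duration_s: float = 90.0,
    specificity_floor: float = 0.0,
) -> list[ChannelAnnotation]:
    """Simulate a panel of reviewers labelling every channel.

    Ambiguity pulls each labelling decision toward a fair coin: on a true
    seizure channel ``P(seizure) = sens*(1-amb) + 0.5*amb``; on a true
    non-seizure channel ``P(seizure) = (1-spec)*(1-amb)
    + 0.5*amb*(1-specificity_floor)``.  ``unsure`` (and ``missing``) verdicts
    override at the profile's rates.  Annotated onsets are the true onset plus
    reviewer bias and gaussian jitter, clipped to the record and rounded to
    0.1 s; jittered onsets falling before the record start are flagged instead
    of clipped.
    """
    if not profiles:
        raise ValueError("at least one reviewer profile is required")
    annotations: list[ChannelAnnotation] = []
    for truth in truths:
        for prof in profiles:
            if prof.missing_rate > 0 and rng.uniform() < prof.missing_rate:
                annotations.append(
                    ChannelAnnotation(prof.reviewer_id, truth.record_id,
                                      truth.channel_index, "missing")
                )
                continue
            if rng.uniform() < prof.unsure_rate:
                annotations.append(
                    ChannelAnnotation(prof.reviewer_id, truth.record_id,
                                      truth.channel_index, "unsure")
                )
                continue
            amb = truth.ambiguity
            if truth.is_seizure:
                p_sz = prof.sensitivity * (1 - amb) + 0.5 * amb
            else:
                p_sz = (1 - prof.specificity) * (1 - amb) + 0.5 * amb * (1 - specificity_floor)
            if rng.uniform() < p_sz:
                if truth.is_seizure:
                    raw = truth.onset_time_s + prof.onset_bias_s
                    if prof.onset_jitter_sd_s > 0:
                        raw += rng.normal(0.0, prof.onset_jitter_sd_s)
                    if raw < 0:
                        annotations.append(
                            ChannelAnnotation(prof.reviewer_id, truth.record_id,
                                              truth.channel_index, "seizure",
                                              onset_before_record_start=True)
                        )
                        continue
                    onset = round(float(np.clip(raw, 0.0, duration_s)), 1)
                else:
                    # false positive: the reviewer picks some onset; no truth
                    # anchors it, so draw uniformly over the record
                    onset = round(float(rng.uniform(0.0, duration_s)), 1)
                annotations.append(
                    ChannelAnnotation(prof.reviewer_id, truth.record_id,
                                      truth.channel_index, "seizure",
                                      onset_time_s=onset)
                )
            else:
                annotations.append(
                    ChannelAnnotation(prof.reviewer_id, truth.record_id,
                                      truth.channel_index, "non_seizure")
                )
    return annotations


def default_reviewer_panel() -> list[ReviewerProfile]:
    """Three reviewers with mildly different operating styles."""
    return [
        ReviewerProfile("R1", sensitivity=0.96, specificity=0.95,
                        unsure_rate=0.015, onset_jitter_sd_s=1.0),
        ReviewerProfile("R2", sensitivity=0.93, specificity=0.97,
                        unsure_rate=0.005, onset_jitter_sd_s=0.8),
        ReviewerProfile("R3", sensitivity=0.97, specificity=0.90,
                        unsure_rate=0.010, onset_jitter_sd_s=1.5,
                        onset_bias_s=-0.3),
    ]


# ---------------------------------------------------------------------------
# EDF round trip (16-bit) — minimal single-file writer/reader
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(record: IEEGRecord, path) -> None:
    """Write one record as a plain EDF file (16-bit, 1-s data records)."""
    fs = record.sample_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sample rate")
    spr = int(round(fs))  # samples per 1-s data record
    n_dr = int(round(record.duration_s))
    ns = len(record.channels)
    phys_max = [max(1e-6, float(np.max(np.abs(ch)))) for ch in record.channels]
    dig_max = 32767
    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad(record.patient_id, 80))
        f.write(_pad(record.record_id, 80))
        f.write(_pad("01.01.20", 8))
        f.write(_pad("00.00.00", 8))
        f.write(_pad(str(256 * (ns + 1)), 8))
        f.write(_pad(f"{record.device_model} {record.record_type}", 44))
        f.write(_pad(str(n_dr), 8))
        f.write(_pad("1", 8))
        f.write(_pad(str(ns), 4))
        for i in range(ns):
            f.write(_pad(f"iEEG{i}", 16))
        for _ in range(ns):
            f.write(_pad("AgAgCl electrode", 80))
        for _ in range(ns):
            f.write(_pad("uV", 8))
        for pm in phys_max:
            f.write(_pad(f"{-pm:.6g}"[:8], 8))
        for pm in phys_max:
            f.write(_pad(f"{pm:.6g}"[:8], 8))
        for _ in range(ns):
            f.write(_pad(str(-dig_max), 8))
        for _ in range(ns):
            f.write(_pad(str(dig_max), 8))
        for _ in range(ns):
            f.write(_pad("", 80))
        for _ in range(ns):
            f.write(_pad(str(spr), 8))
        for _ in range(ns):
            f.write(_pad("", 32))
        # physical max as written (8 ascii chars) may lose precision; re-read
        # it for exact quantization symmetry with the reader
        pm_written = [float(f"{pm:.6g}"[:8]) for pm in phys_max]
        digital = [
            np.clip(np.round(ch / pm * dig_max), -dig_max, dig_max).astype("<i2")
            for ch, pm in zip(record.channels, pm_written)
        ]
        for dr in range(n_dr):
            for ch in digital:
                f.write(ch[dr * spr:(dr + 1) * spr].tobytes())


def read_edf(path) -> IEEGRecord:
    """Read an EDF file written by :func:`write_edf` back into a record."""
    with open(path, "rb") as f:
        header = f.read(256)
        patient_id = header[8:88].decode("ascii").strip()
        record_id = header[88:168].decode("ascii").strip()
        reserved = header[192:236].decode("ascii").split()
        n_dr = int(header[236:244])
        dr_dur = float(header[244:252])
        ns = int(header[252:256])
        sig = f.read(256 * ns)
        off = 0
        off += 16 * ns  # labels
        off += 80 * ns  # transducer
        off += 8 * ns   # dimension
        phys_min = [float(sig[off + i * 8: off + (i + 1) * 8]) for i in range(ns)]
        off += 8 * ns
        phys_max = [float(sig[off + i * 8: off + (i + 1) * 8]) for i in range(ns)]
        off += 8 * ns
        dig_min = [int(sig[off + i * 8: off + (i + 1) * 8]) for i in range(ns)]
        off += 8 * ns
        dig_max = [int(sig[off + i * 8: off + (i + 1) * 8]) for i in range(ns)]
        off += 8 * ns
        off += 80 * ns  # prefiltering
        spr = [int(sig[off + i * 8: off + (i + 1) * 8]) for i in range(ns)]
        off += 8 * ns
        data = np.frombuffer(f.read(), dtype="<i2")
    per_dr = sum(spr)
    data = data[: n_dr * per_dr].reshape(n_dr, per_dr)
    channels = []
    pos = 0
    for i in range(ns):
        dig = data[:, pos: pos + spr[i]].reshape(-1).astype(float)
        pos += spr[i]
        scale = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        channels.append((dig - dig_min[i]) * scale + phys_min[i])
    device = reserved[0] if reserved else "RNS-320"
    rtype = reserved[1] if len(reserved) > 1 else "long_episode"
    fs = spr[0] / dr_dur
    return IEEGRecord(
        record_id=record_id,
        patient_id=patient_id,
        device_model=device,
        record_type=rtype,
        sample_rate_hz=fs,
        duration_s=n_dr * dr_dur,
        trigger_time_s=min(60.0, n_dr * dr_dur),
        channels=channels,
    )


# ---------------------------------------------------------------------------
# HDF5 cohort layout
# ---------------------------------------------------------------------------

def write_cohort_h5(records: Sequence[IEEGRecord],
                    truths: Sequence[ChannelTruth], path) -> None:
    """Cohort-level HDF5 layout: one dataset per record plus a truth table."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("records")
        for rec in records:
            d = grp.create_dataset(rec.record_id, data=np.asarray(rec.channels))
            d.attrs.update({
                "patient_id": rec.patient_id,
                "device_model": rec.device_model,
                "record_type": rec.record_type,
                "sample_rate_hz": rec.sample_rate_hz,
                "duration_s": rec.duration_s,
                "trigger_time_s": rec.trigger_time_s,
                "lead_location": rec.lead_location,
            })
        tg = f.create_group("truths")
        tg.create_dataset("record_id",
                          data=np.array([t.record_id for t in truths], dtype="S"))
        tg.create_dataset("channel_index",
                          data=np.array([t.channel_index for t in truths]))
        tg.create_dataset("is_seizure",
                          data=np.array([t.is_seizure for t in truths]))
        tg.create_dataset(
            "onset_time_s",
            data=np.array([np.nan if t.onset_time_s is None else t.onset_time_s
                           for t in truths]))
        tg.create_dataset("ambiguity", data=np.array([t.ambiguity for t in truths]))


def read_cohort_h5(path) -> tuple[list[IEEGRecord], list[ChannelTruth]]:
    records, truths = [], []
    with h5py.File(path, "r") as f:
        for rid in sorted(f["records"]):
            d = f["records"][rid]
            records.append(IEEGRecord(
                record_id=rid,
                patient_id=d.attrs["patient_id"],
                device_model=d.attrs["device_model"],
                record_type=d.attrs["record_type"],
                sample_rate_hz=float(d.attrs["sample_rate_hz"]),
                duration_s=float(d.attrs["duration_s"]),
                trigger_time_s=float(d.attrs["trigger_time_s"]),
                channels=list(np.asarray(d)),
                lead_location=str(d.attrs["lead_location"]),
            ))
        tg = f["truths"]
        rids = [s.decode() for s in tg["record_id"][()]]
        onsets = tg["onset_time_s"][()]
        for i, rid in enumerate(rids):
            is_sz = bool(tg["is_seizure"][i])
            truths.append(ChannelTruth(
                rid, int(tg["channel_index"][i]), is_sz,
                None if not is_sz else float(onsets[i]),
                float(tg["ambiguity"][i]),
            ))
    return records, truths


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

_ANN_COLS = ["record_id", "channel_index", "reviewer_id", "label",
             "onset_time_s", "onset_before_record_start"]


def annotations_to_frame(annotations: Iterable[ChannelAnnotation]) -> pd.DataFrame:
    rows = [
        (a.record_id, a.channel_index, a.reviewer_id, a.label,
         np.nan if a.onset_time_s is None else a.onset_time_s,
         a.onset_before_record_start)
        for a in annotations
    ]
    return pd.DataFrame(rows, columns=_ANN_COLS)


def annotations_to_csv(annotations: Iterable[ChannelAnnotation], path) -> None:
    annotations_to_frame(annotations).to_csv(path, index=False)


def annotations_from_csv(path) -> list[ChannelAnnotation]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        onset = None if pd.isna(row.onset_time_s) else round(float(row.onset_time_s), 1)
        out.append(ChannelAnnotation(
            str(row.reviewer_id), str(row.record_id), int(row.channel_index),
            str(row.label), onset, bool(row.onset_before_record_start)))
    return out


def truths_to_csv(truths: Iterable[ChannelTruth], path) -> None:
    pd.DataFrame(
        [(t.record_id, t.channel_index, t.is_seizure,
          np.nan if t.onset_time_s is None else t.onset_time_s, t.ambiguity)
         for t in truths],
        columns=["record_id", "channel_index", "is_seizure", "onset_time_s", "ambiguity"],
    ).to_csv(path, index=False)


def truths_from_csv(path) -> list[ChannelTruth]:
    df = pd.read_csv(path)
    return [
        ChannelTruth(
            str(r.record_id), int(r.channel_index), bool(r.is_seizure),
            None if pd.isna(r.onset_time_s) else float(r.onset_time_s),
            float(r.ambiguity))
        for r in df.itertuples(index=False)
    ]
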