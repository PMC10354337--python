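"""Spectrogram featurization of single iEEG channels.

One channel of raw samples becomes a log-power spectrogram (Hann taper,
one-sided periodogram per frame, window 256 samples / step 128 at 250 Hz)
and then a normalized, resized image tensor for the networks.  The
frame-center time convention gives an exact, invertible frame <-> time
mapping used to align onset labels with spectrogram columns.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import h5py
import numpy as np
from scipy import signal as sps
from skimage.transform import resize as _sk_resize

__all__ = [
    "Spectrogram",
    "ModelInput",
    "compute_spectrogram",
    "to_model_input",
    "time_to_frame",
    "frame_to_time",
    "export_png",
    "save_model_inputs",
    "load_model_inputs",
]

LOG_FLOOR = 1e-12


@dataclass
class Spectrogram:
    power: np.ndarray          # [n_freq_bins, n_frames], 10*log10(P + eps)
    window_size: int
    step_size: int
    sample_rate_hz: float
    freq_axis_hz: np.ndarray
    frame_times_s: np.ndarray  # frame-center times

    @property
    def n_frames(self) -> int:
        return self.power.shape[1]

    @property
    def n_freq_bins(self) -> int:
        return self.power.shape[0]


@dataclass
class ModelInput:
    image: np.ndarray  # [H, W, C] in [0, 1]
    record_id: str = ""
    channel_index: int = -1
    out_hw: tuple = (32, 48)


def compute_spectrogram(
    samples: np.ndarray,
    sample_rate_hz: float,
    window_size: int = 256,
    step_size: int = 128,
) -> Spectrogram:
    """Hann-tapered one-sided log-power spectrogram.

    Frame ``i`` covers samples ``[i*step, i*step + window)``; its timestamp is
    the window center ``(i*step + window/2) / fs``.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("samples must be a 1-D vector")
    if x.size < window_size:
        raise ValueError(f"need at least {window_size} samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples contain NaN or infinite values")
    freqs, times, Sxx = sps.spectrogram(
        x,
        fs=sample_rate_hz,
        window="hann",
        nperseg=window_size,
        noverlap=window_size - step_size,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    power = 10.0 * np.log10(Sxx + LOG_FLOOR)
    return Spectrogram(
        power=power,
        window_size=window_size,
        step_size=step_size,
        sample_rate_hz=sample_rate_hz,
        freq_axis_hz=freqs,
        frame_times_s=times,
    )


def to_model_input(
    spec: Spectrogram,
    out_hw: tuple = (32, 48),
    per_image_norm: bool = True,
    n_image_channels: int = 1,
    record_id: str = "",
    channel_index: int = -1,
) -> ModelInput:
    """Min-max normalize to [0, 1] and bilinear-resize to ``out_hw``.

    A constant (degenerate) spectrogram maps to an all-0.5 image with a
    warning rather than dividing by zero.
    """
    img = np.asarray(spec.power, dtype=float)
    if per_image_norm:
        lo, hi = float(img.min()), float(img.max())
        if hi - lo < 1e-12:
            warnings.warn("degenerate (constant) spectrogram; mapping to 0.5")
            img = np.full_like(img, 0.5)
        else:
            img = (img - lo) / (hi - lo)
    img = _sk_resize(img, out_hw, order=1, preserve_range=True,
                     anti_aliasing=True)
    img = np.clip(img, 0.0, 1.0)
    img = np.repeat(img[:, :, None], n_image_channels, axis=2)
    return ModelInput(image=img, record_id=record_id,
                      channel_index=channel_index, out_hw=tuple(out_hw))


def time_to_frame(spec: Spectrogram, t_s: float) -> int:
    """Index of the frame whose center is nearest ``t_s`` (clipped to range)."""
    n_samples = (spec.n_frames - 1) * spec.step_size + spec.window_size
    if not 0.0 <= t_s <= n_samples / spec.sample_rate_hz:
        raise ValueError(f"time {t_s} s outside the record")
    i = round((t_s * spec.sample_rate_hz - spec.window_size / 2) / spec.step_size)
    return int(np.clip(i, 0, spec.n_frames - 1))


def frame_to_time(spec: Spectrogram, i: int) -> float:
    """Center time of frame ``i`` in seconds."""
    if not 0 <= i < spec.n_frames:
        raise ValueError(f"frame index {i} out of range")
    return float(spec.frame_times_s[i])


def export_png(spec: Spectrogram, path, cmap: str = "viridis") -> None:
    """Write the spectrogram as a PNG image for visual inspection."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(path, spec.power[::-1, :], cmap=cmap)


# ---------------------------------------------------------------------------
# HDF5 cache of model-input tensors
# ---------------------------------------------------------------------------

def _transform_hash(out_hw, per_image_norm, n_image_channels) -> str:
    key = f"{tuple(out_hw)}|{per_image_norm}|{n_image_channels}"
    return hashlib.sha256(key.encode()).hexdigest()[:12]


def save_model_inputs(inputs: list, path, out_hw=(32, 48),
                      per_image_norm=True, n_image_channels=1) -> None:
    h = _transform_hash(out_hw, per_image_norm, n_image_channels)
    with h5py.File(path, "w") as f:
        grp = f.create_group(h)
        for mi in inputs:
            key = f"{mi.record_id}__{mi.channel_index}"
            grp.create_dataset(key, data=mi.image)


def load_model_inputs(path, out_hw=(32, 48), per_image_norm=True,
                      n_image_channels=1) -> list:
    h = _transform_hash(out_hw, per_image_norm, n_image_channels)
    out = []
    with h5py.File(path, "r") as f:
        if h not in f:
            raise KeyError("no cached tensors for this transform")
        for key in sorted(f[h]):
            rid, ch = key.rsplit("__", 1)
            out.append(ModelInput(image=np.asarray(f[h][key]), record_id=rid,
                                  channel_index=int(ch), out_hw=tuple(out_hw)))
    return out
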