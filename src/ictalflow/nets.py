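"""Small convolutional networks in NumPy with an Adam optimizer.

This is the desk-scale backbone behind the seizure classifier and the onset
regressor: two 3x3 convolution blocks with leaky-ReLU activations and max
pooling produce a feature map; averaging over the frequency axis and
projecting each time column through a dense layer yields a per-column
"ictal evidence" logit profile ``s``.  The two task heads read that shared
profile differently:

* classification — the logit of the seizure probability is an affine
  function of the *smooth range* of ``s`` (smooth-max plus smooth-max of
  ``-s``): a channel is a seizure when its evidence profile has contrast
  between a pre-onset and an ictal regime, which is exactly what survives
  per-image min-max normalization of the spectrogram;
* onset regression — a softmax over the first differences of ``s`` (the
  evidence *rises*) gives attention weights over column boundaries, whose
  positional expectation is the normalized onset time.

Because both heads consume the same evidence profile, initializing the
regressor from a trained classifier transfers not only generic filters but
an already-informative step profile, which is what makes task pretraining
pay off at small sample sizes.  Forward and backward passes are written
against im2col matrices, so training a few hundred spectrogram images for
tens of epochs takes seconds on one CPU core.  All initialization and
batching randomness flows through caller-supplied NumPy generators, making
training bit-reproducible.
"""

from __future__ import annotations

import copy

import numpy as np

__all__ = [
    "ConvTrunk",
    "EvidenceClassifier",
    "OnsetRegressor",
    "Adam",
    "bce_loss_grad",
    "huber_loss_grad",
    "orient_transferred_head",
    "pretrain_generic_backbone",
]

LEAK = 0.01          # leaky-ReLU negative slope (guards against dead units)
RANGE_TAU = 0.5      # smooth-max temperature of the classification head
RISE_GAIN = 4.0      # softmax sharpness over evidence rises (regression)


def _lrelu(z):
    return np.where(z > 0, z, LEAK * z)


def _dlrelu(z):
    return np.where(z > 0, 1.0, LEAK)


# ---------------------------------------------------------------------------
# im2col helpers (3x3, stride 1, zero padding 1)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, H, W, C) -> (N*H*W, 9*C) patch matrix for 3x3 same-convolution."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = np.empty((n, h, w, 9 * c), dtype=x.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            cols[..., k * c:(k + 1) * c] = xp[:, di:di + h, dj:dj + w, :]
            k += 1
    return cols.reshape(n * h * w, 9 * c)


def _col2im(cols: np.ndarray, shape) -> np.ndarray:
    """Adjoint of :func:`_im2col` — scatter patch gradients back."""
    n, h, w, c = shape
    cols = cols.reshape(n, h, w, 9 * c)
    out = np.zeros((n, h + 2, w + 2, c), dtype=cols.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            out[:, di:di + h, dj:dj + w, :] += cols[..., k * c:(k + 1) * c]
            k += 1
    return out[:, 1:-1, 1:-1, :]


def _maxpool(x: np.ndarray):
    n, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    v = x[:, :h2 * 2, :w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
    flat = v.transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxpool_back(dout: np.ndarray, idx: np.ndarray, shape) -> np.ndarray:
    n, h, w, c = shape
    h2, w2 = h // 2, w // 2
    flat = np.zeros((n, h2, w2, c, 4), dtype=dout.dtype)
    np.put_along_axis(flat, idx[..., None], dout[..., None], axis=-1)
    v = flat.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    dx = np.zeros(shape, dtype=dout.dtype)
    dx[:, :h2 * 2, :w2 * 2, :] = v.reshape(n, h2 * 2, w2 * 2, c)
    return dx


def _softmax_rows(v: np.ndarray) -> np.ndarray:
    e = np.exp(v - v.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# shared trunk + evidence projection
# ---------------------------------------------------------------------------

class ConvTrunk:
    """Two conv blocks plus the dense evidence projection shared by both heads.

    Parameter keys: ``conv1_W/b``, ``conv2_W/b`` (the backbone) and
    ``head_W/b`` (the dense evidence projection, C2 -> 1, applied per time
    column after frequency pooling).  Subclasses add head-specific scalars.
    """

    BACKBONE_KEYS = ("conv1_W", "conv1_b", "conv2_W", "conv2_b")
    TRANSFER_KEYS = BACKBONE_KEYS + ("head_W", "head_b")

    def __init__(self, input_hw=(32, 48), in_channels=1, conv_channels=(8, 16),
                 rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.input_hw = tuple(input_hw)
        self.in_channels = in_channels
        self.conv_channels = tuple(conv_channels)
        c1, c2 = conv_channels

        def he(shape, fan_in):
            return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

        self.params = {
            "conv1_W": he((9 * in_channels, c1), 9 * in_channels),
            "conv1_b": np.zeros(c1),
            "conv2_W": he((9 * c1, c2), 9 * c1),
            "conv2_b": np.zeros(c2),
            "head_W": he((c2, 1), c2),
            "head_b": np.zeros(1),
        }

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def get_weights(self) -> dict:
        return copy.deepcopy(self.params)

    def set_weights(self, weights: dict) -> None:
        if set(weights) != set(self.params):
            raise ValueError("weight keys do not match this architecture")
        for k, v in weights.items():
            if np.shape(v) != self.params[k].shape:
                raise ValueError(f"shape mismatch for {k}")
        self.params = copy.deepcopy(weights)

    def backbone_weights(self) -> dict:
        return {k: self.params[k].copy() for k in self.BACKBONE_KEYS}

    def transferable_weights(self) -> dict:
        return {k: self.params[k].copy() for k in self.TRANSFER_KEYS}

    def load_transferable(self, weights: dict) -> None:
        for k in self.TRANSFER_KEYS:
            if k in weights:
                if weights[k].shape != self.params[k].shape:
                    raise ValueError(f"transfer shape mismatch for {k}")
                self.params[k] = weights[k].copy()

    # -- shared forward/backward pieces -------------------------------------
    def _trunk(self, x: np.ndarray) -> dict:
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:3] != self.input_hw or x.shape[3] != self.in_channels:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match "
                f"{self.input_hw + (self.in_channels,)}")
        p = self.params
        n = x.shape[0]
        h, w = self.input_hw
        cols1 = _im2col(x)
        z1 = (cols1 @ p["conv1_W"] + p["conv1_b"]).reshape(
            n, h, w, self.conv_channels[0])
        a1 = _lrelu(z1)
        p1, idx1 = _maxpool(a1)
        cols2 = _im2col(p1)
        z2 = (cols2 @ p["conv2_W"] + p["conv2_b"]).reshape(
            n, p1.shape[1], p1.shape[2], self.conv_channels[1])
        a2 = _lrelu(z2)
        p2, idx2 = _maxpool(a2)
        u = p2.mean(axis=1)  # frequency-pooled column features (n, W/4, C2)
        s = (u @ p["head_W"]).squeeze(-1) + p["head_b"]  # evidence profile
        return dict(x=x, cols1=cols1, z1=z1, p1=p1, idx1=idx1, cols2=cols2,
                    z2=z2, a2=a2, p2=p2, idx2=idx2, u=u, s=s)

    def _evidence_back(self, cache: dict, ds: np.ndarray) -> dict:
        """Backprop from dL/ds through the projection and both conv blocks."""
        p = self.params
        g = {}
        g["head_b"] = np.array([ds.sum()])
        g["head_W"] = (cache["u"] * ds[:, :, None]).sum(axis=(0, 1))[:, None]
        du = ds[:, :, None] @ p["head_W"].T[None]
        h2 = cache["p2"].shape[1]
        dp2 = np.repeat(du[:, None, :, :], h2, axis=1) / h2
        da2 = _maxpool_back(dp2, cache["idx2"], cache["a2"].shape)
        dz2 = da2 * _dlrelu(cache["z2"])
        dz2c = dz2.reshape(-1, self.conv_channels[1])
        g["conv2_W"] = cache["cols2"].T @ dz2c
        g["conv2_b"] = dz2c.sum(axis=0)
        dp1 = _col2im(dz2c @ p["conv2_W"].T, cache["p1"].shape)
        da1 = _maxpool_back(
            dp1, cache["idx1"],
            (cache["x"].shape[0], *self.input_hw, self.conv_channels[0]))
        dz1 = da1 * _dlrelu(cache["z1"])
        dz1c = dz1.reshape(-1, self.conv_channels[0])
        g["conv1_W"] = cache["cols1"].T @ dz1c
        g["conv1_b"] = dz1c.sum(axis=0)
        return g

    def evidence_profile(self, x: np.ndarray) -> np.ndarray:
        """Per-column ictal evidence logits (n, W/4) — for inspection."""
        return self._trunk(x)["s"]


class EvidenceClassifier(ConvTrunk):
    """Seizure/non-seizure head: sigmoid of the smooth evidence range."""

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        self.params["cal_a"] = np.array([1.0])
        self.params["cal_b"] = np.array([-1.0])

    @staticmethod
    def _smoothmax(v: np.ndarray) -> np.ndarray:
        m = v.max(axis=1, keepdims=True)
        return (m.ravel()
                + RANGE_TAU * np.log(np.exp((v - m) / RANGE_TAU).sum(axis=1))
                - RANGE_TAU * np.log(v.shape[1]))

    def forward(self, x, want_cache: bool = False):
        c = self._trunk(x)
        p = self.params
        s = c["s"]
        rng_ = self._smoothmax(s) + self._smoothmax(-s)
        logit = p["cal_a"][0] * rng_ + p["cal_b"][0]
        prob = 1.0 / (1.0 + np.exp(-logit))
        if not want_cache:
            return prob
        c.update(range=rng_, prob=prob)
        return prob, c

    def backward(self, cache: dict, dlogit: np.ndarray) -> dict:
        p = self.params
        s = cache["s"]
        g = {
            "cal_a": np.array([float((dlogit * cache["range"]).sum())]),
            "cal_b": np.array([float(dlogit.sum())]),
        }
        w_hi = _softmax_rows(s / RANGE_TAU)
        w_lo = _softmax_rows(-s / RANGE_TAU)
        ds = (w_hi - w_lo) * (p["cal_a"][0] * dlogit)[:, None]
        g.update(self._evidence_back(cache, ds))
        return g


class OnsetRegressor(ConvTrunk):
    """Onset head: positional expectation over softmaxed evidence rises.

    The output is the normalized onset position in [0, 1]; multiply by the
    record duration for seconds.
    """

    def __init__(self, *args, gain: float = RISE_GAIN, **kwargs):
        super().__init__(*args, **kwargs)
        self.gain = gain
        w2 = self.input_hw[1] // 4
        # candidate onset positions: boundaries between adjacent columns
        self.positions = np.arange(1, w2) / w2

    def forward(self, x, want_cache: bool = False):
        c = self._trunk(x)
        s = c["s"]
        d = s[:, 1:] - s[:, :-1]
        alpha = _softmax_rows(self.gain * d)
        out = (alpha * self.positions).sum(axis=1)
        if not want_cache:
            return out
        c.update(alpha=alpha, out=out)
        return out, c

    def backward(self, cache: dict, dout: np.ndarray) -> dict:
        alpha, out = cache["alpha"], cache["out"]
        dd = self.gain * alpha * (self.positions[None, :] - out[:, None]) \
            * dout[:, None]
        ds = np.zeros_like(cache["s"])
        ds[:, 1:] += dd
        ds[:, :-1] -= dd
        return self._evidence_back(cache, ds)


def orient_transferred_head(clf_weights: dict, regressor: OnsetRegressor,
                            x_train: np.ndarray, y_train_norm: np.ndarray) -> None:
    """Resolve the sign ambiguity of a transferred evidence projection.

    A trained classifier's evidence profile separates pre-onset from ictal
    columns, but whether ictal columns score *high* or *low* is arbitrary
    (the smooth-range head is symmetric in the sign of ``s``).  The onset
    regressor reads evidence *rises*, so pick the orientation whose
    epoch-0 predictions better fit the training onsets.  Deterministic and
    uses training items only.
    """
    best = None
    for sign in (1.0, -1.0):
        trial = {k: (v * sign if k.startswith("head") else v)
                 for k, v in clf_weights.items()
                 if k in ConvTrunk.TRANSFER_KEYS}
        regressor.load_transferable(trial)
        err = float(np.mean((regressor.forward(x_train) - y_train_norm) ** 2))
        if best is None or err < best[0]:
            best = (err, trial)
    regressor.load_transferable(best[1])


# ---------------------------------------------------------------------------
# losses (return loss value and dL/d(head pre-activation))
# ---------------------------------------------------------------------------

def bce_loss_grad(prob: np.ndarray, y: np.ndarray, sample_weight=None):
    """Binary cross-entropy on sigmoid outputs; gradient w.r.t. the logit."""
    prob = np.clip(prob, 1e-12, 1 - 1e-12)
    w = np.ones_like(prob) if sample_weight is None else np.asarray(sample_weight)
    w = w / w.sum()
    loss = -np.sum(w * (y * np.log(prob) + (1 - y) * np.log(1 - prob)))
    grad = w * (prob - y)  # d(BCE)/d(logit), already weighted
    return loss, grad


def huber_loss_grad(pred: np.ndarray, y: np.ndarray, delta: float = 0.5):
    """Huber loss on normalized onsets; quadratic within ``delta``.

    With the default delta of 0.5 (half the record) virtually all residuals
    fall in the quadratic regime, while gross outliers keep bounded
    influence.
    """
    r = pred - y
    a = np.abs(r)
    quad = a <= delta
    loss = np.mean(np.where(quad, 0.5 * r ** 2, delta * (a - 0.5 * delta)))
    grad = np.where(quad, r, delta * np.sign(r)) / r.size
    return loss, grad


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: dict, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, gk in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk ** 2
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# generic pretraining (texture discrimination)
# ---------------------------------------------------------------------------

def pretrain_generic_backbone(input_hw=(32, 48), in_channels=1,
                              conv_channels=(8, 16), seed=0,
                              n_images=160, epochs=10) -> EvidenceClassifier:
    """Train a classifier on a synthetic texture-discrimination task.

    Returns a generically pretrained network (oriented gratings vs smoothed
    noise) whose filters respond to oriented energy but which has never seen
    ictal data — the desk-scale analogue of an off-the-shelf natural-image
    initialization.
    """
    from scipy.signal import convolve2d

    rng = np.random.default_rng(seed)
    h, w = input_hw
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    X = np.empty((n_images, h, w, in_channels))
    y = np.empty(n_images)
    smooth_kernel = np.outer(np.hanning(7), np.hanning(7))
    smooth_kernel /= smooth_kernel.sum()
    for i in range(n_images):
        if i % 2 == 0:  # smoothed noise
            img = convolve2d(rng.standard_normal((h, w)), smooth_kernel,
                             mode="same")
            y[i] = 0
        else:  # oriented grating
            theta = rng.uniform(0, np.pi)
            f = rng.uniform(0.15, 0.5)
            img = np.sin(2 * np.pi * f * (ii * np.cos(theta) + jj * np.sin(theta))
                         + rng.uniform(0, 2 * np.pi))
            img += 0.3 * rng.standard_normal((h, w))
            y[i] = 1
        img = (img - img.min()) / (np.ptp(img) + 1e-12)
        X[i] = np.repeat(img[:, :, None], in_channels, axis=2)
    net = EvidenceClassifier(input_hw, in_channels, conv_channels, rng=rng)
    opt = Adam(net.params, lr=1e-2)
    idx = np.arange(n_images)
    for _ in range(epochs):
        rng.shuffle(idx)
        for start in range(0, n_images, 16):
            b = idx[start:start + 16]
            prob, cache = net.forward(X[b], want_cache=True)
            _, grad = bce_loss_grad(prob, y[b])
            opt.step(net.params, net.backward(cache, grad))
    return net
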