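"""Lightweight convolutional patch classifier (CNNlw).

Architecture: three convolution stages (kernel, stride, filters) =
(7, 2, 40), (5, 2, 60), (3, 2, 120), each with same-padding followed by
2x2 max-pooling, then two fully connected stages of 100 and 50 units.
Hidden activations are sigmoid; a final dense layer with softmax gives
the class posterior.  With a 64 px input side the spatial ladder is
64 -> 32 -> 16 -> 8 -> 4 -> 2 -> 1, flattening to 120 features.

Training uses cross-entropy with adaptive moment estimation
(beta1 = 0.9, beta2 = 0.999, eps = 1e-8) and zero-mean Gaussian weight
initialisation.  The network is implemented directly on numpy
(im2col convolutions), which is ample for 64 px patches, and is wrapped
in a scikit-learn style estimator, :class:`CNNPatchClassifier`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .classifiers import resize_patch

ADAM_BETA1 = 0.9
ADAM_BETA2 = 0.999
ADAM_EPS = 1e-8


@dataclass(frozen=True)
class CnnLwSpec:
    """Layer configuration of the lightweight CNN."""

    conv_stages: tuple[tuple[int, int, int], ...] = ((7, 2, 40), (5, 2, 60), (3, 2, 120))
    pool_size: int = 2
    fc_units: tuple[int, ...] = (100, 50)
    input_side: int = 64

    def spatial_ladder(self) -> list[int]:
        """Spatial side after each conv and pool stage; raises if any
        stage would need fractional dimensions."""
        side = self.input_side
        ladder = [side]
        for k, s, _ in self.conv_stages:
            if side % s != 0:
                raise ValueError(
                    f"input side {self.input_side} gives non-integer conv output ({side}/{s})"
                )
            side //= s  # same padding: out = side / stride
            ladder.append(side)
            if side % self.pool_size != 0:
                raise ValueError(
                    f"input side {self.input_side} gives non-integer pool output "
                    f"({side}/{self.pool_size})"
                )
            side //= self.pool_size
            ladder.append(side)
        if side < 1:
            raise ValueError("spatial dimensions collapsed below 1")
        return ladder

    @property
    def flat_features(self) -> int:
        side = self.spatial_ladder()[-1]
        return side * side * self.conv_stages[-1][2]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _same_pad(side: int, k: int, s: int) -> tuple[int, int]:
    out = side // s
    total = max((out - 1) * s + k - side, 0)
    return total // 2, total - total // 2


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, k: int, s: int):
    n, side = x.shape[0], x.shape[1]
    before, after = _same_pad(side, k, s)
    xp = np.pad(x, ((0, 0), (before, after), (before, after), (0, 0)), mode="constant")
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    win = win[:, ::s, ::s]  # (n, out, out, c, k, k)
    out = win.shape[1]
    cols = np.moveaxis(win, 3, 5).reshape(n * out * out, -1)  # (n*out*out, k*k*c)
    y = (cols @ w + b).reshape(n, out, out, -1)
    return y, (cols, xp.shape, before, out)


def _conv_backward(dy: np.ndarray, cache, w: np.ndarray, k: int, s: int, c_in: int):
    cols, xp_shape, before, out = cache
    n = dy.shape[0]
    dflat = dy.reshape(n * out * out, -1)
    dw = cols.T @ dflat
    db = dflat.sum(axis=0)
    dcols = (dflat @ w.T).reshape(n, out, out, k, k, c_in)
    dxp = np.zeros(xp_shape)
    for di in range(k):
        for dj in range(k):
            dxp[:, di : di + (out - 1) * s + 1 : s, dj : dj + (out - 1) * s + 1 : s, :] += dcols[
                :, :, :, di, dj, :
            ]
    side = out * s  # same padding: unpadded input side
    dx = dxp[:, before : before + side, before : before + side, :]
    return dx, dw, db


def _pool_forward(x: np.ndarray, p: int):
    n, side, _, c = x.shape
    xr = x.reshape(n, side // p, p, side // p, p, c)
    y = xr.max(axis=(2, 4))
    mask = xr == y[:, :, None, :, None, :]
    return y, mask


def _pool_backward(dy: np.ndarray, mask: np.ndarray, p: int):
    n, out, _, c = dy.shape[0], dy.shape[1], dy.shape[2], dy.shape[3]
    d = mask * dy[:, :, None, :, None, :]
    return d.reshape(n, out * p, out * p, c)


class CNNLw:
    """The raw network: parameters, forward/backward, Adam steps."""

    def __init__(
        self,
        num_classes: int,
        spec: CnnLwSpec | None = None,
        init_std: float = 1.0,
        seed: int = 0,
    ):
        self.spec = spec or CnnLwSpec()
        self.spec.spatial_ladder()  # validates the configuration
        self.num_classes = int(num_classes)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = 3
        for i, (k, s, f) in enumerate(self.spec.conv_stages):
            self.params[f"conv{i}_w"] = rng.normal(0.0, init_std, (k * k * c_in, f))
            self.params[f"conv{i}_b"] = np.zeros(f)
            c_in = f
        feat = self.spec.flat_features
        dims = (feat, *self.spec.fc_units, self.num_classes)
        for i in range(len(dims) - 1):
            self.params[f"fc{i}_w"] = rng.normal(0.0, init_std, (dims[i], dims[i + 1]))
            self.params[f"fc{i}_b"] = np.zeros(dims[i + 1])
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    def forward(self, x: np.ndarray, want_cache: bool = False):
        cache: list = []
        h = x
        for i, (k, s, _) in enumerate(self.spec.conv_stages):
            c_in = h.shape[-1]
            z, conv_cache = _conv_forward(h, self.params[f"conv{i}_w"], self.params[f"conv{i}_b"], k, s)
            a = _sigmoid(z)
            p, mask = _pool_forward(a, self.spec.pool_size)
            cache.append(("conv", i, k, s, c_in, conv_cache, a, mask))
            h = p
        n = h.shape[0]
        h = h.reshape(n, -1)
        n_fc = len(self.spec.fc_units) + 1
        for i in range(n_fc):
            z = h @ self.params[f"fc{i}_w"] + self.params[f"fc{i}_b"]
            if i < n_fc - 1:
                a = _sigmoid(z)
                cache.append(("fc", i, h, a))
                h = a
            else:
                cache.append(("fc_out", i, h))
                h = z
        return (h, cache) if want_cache else h

    @staticmethod
    def softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Cross-entropy loss and parameter gradients for a batch."""
        logits, cache = self.forward(x, want_cache=True)
        n = x.shape[0]
        probs = self.softmax(logits)
        loss = -np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean()
        grads: dict[str, np.ndarray] = {}
        dz = probs.copy()
        dz[np.arange(n), y] -= 1.0
        dz /= n
        dh = dz
        for entry in reversed(cache):
            if entry[0] == "fc_out":
                _, i, h_in = entry
                grads[f"fc{i}_w"] = h_in.T @ dh
                grads[f"fc{i}_b"] = dh.sum(axis=0)
                dh = dh @ self.params[f"fc{i}_w"].T
            elif entry[0] == "fc":
                _, i, h_in, a = entry
                dz = dh * a * (1.0 - a)
                grads[f"fc{i}_w"] = h_in.T @ dz
                grads[f"fc{i}_b"] = dz.sum(axis=0)
                dh = dz @ self.params[f"fc{i}_w"].T
            else:
                _, i, k, s, c_in, conv_cache, a, mask = entry
                if dh.ndim == 2:  # arriving from the first fc layer
                    side = a.shape[1] // self.spec.pool_size
                    dh = dh.reshape(dh.shape[0], side, side, -1)
                da = _pool_backward(dh, mask, self.spec.pool_size)
                dz = da * a * (1.0 - a)
                dx, dw, db = _conv_backward(dz, conv_cache, self.params[f"conv{i}_w"], k, s, c_in)
                grads[f"conv{i}_w"] = dw
                grads[f"conv{i}_b"] = db
                dh = dx
        return loss, grads

    def adam_step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        self._adam_t += 1
        t = self._adam_t
        for key, g in grads.items():
            m = self._adam_m[key]
            v = self._adam_v[key]
            m *= ADAM_BETA1
            m += (1 - ADAM_BETA1) * g
            v *= ADAM_BETA2
            v += (1 - ADAM_BETA2) * g * g
            mhat = m / (1 - ADAM_BETA1**t)
            vhat = v / (1 - ADAM_BETA2**t)
            self.params[key] -= lr * mhat / (np.sqrt(vhat) + ADAM_EPS)

    def save(self, path: str | Path) -> None:
        meta = {
            "num_classes": self.num_classes,
            "input_side": self.spec.input_side,
        }
        np.savez(path, _meta=np.array([meta["num_classes"], meta["input_side"]]), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "CNNLw":
        data = np.load(path)
        num_classes, input_side = (int(v) for v in data["_meta"])
        net = cls(num_classes, spec=CnnLwSpec(input_side=input_side), init_std=0.0)
        for key in net.params:
            net.params[key] = data[key]
        return net


class CNNPatchClassifier(ClassifierMixin, BaseEstimator):
    """scikit-learn style wrapper around :class:`CNNLw`.

    Parameters
    ----------
    patch_side : input side in pixels (must yield an integer spatial
        ladder; 64 by default).
    n_steps : number of Adam mini-batch steps.
    batch_size, learning_rate : optimisation hyper-parameters.
    init_std : std of the zero-mean Gaussian weight initialisation.
        The published configuration uses 1.0; smaller values train
        faster with sigmoid units.
    random_state : seed for initialisation and batch sampling.
    """

    def __init__(
        self,
        patch_side: int = 64,
        n_steps: int = 300,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        init_std: float = 1.0,
        random_state: int = 0,
    ):
        self.patch_side = patch_side
        self.n_steps = n_steps
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.init_std = init_std
        self.random_state = random_state

    def _as_batch(self, X) -> np.ndarray:
        arr = np.asarray(X, dtype=np.float64)
        if arr.ndim == 3:
            arr = arr[None]
        if arr.shape[1] != self.patch_side:
            arr = np.stack([resize_patch(p.astype(np.uint8), self.patch_side) for p in arr])
            arr = arr.astype(np.float64)
        return arr / 255.0

    def fit(self, X, y) -> "CNNPatchClassifier":
        X = self._as_batch(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        y_idx = np.searchsorted(self.classes_, y)
        spec = CnnLwSpec(input_side=self.patch_side)
        self.net_ = CNNLw(
            len(self.classes_), spec=spec, init_std=self.init_std, seed=self.random_state
        )
        rng = np.random.default_rng(self.random_state + 1)
        n = X.shape[0]
        self.loss_curve_ = []
        for _ in range(self.n_steps):
            idx = rng.choice(n, size=min(self.batch_size, n), replace=False)
            loss, grads = self.net_.loss_and_grads(X[idx], y_idx[idx])
            self.net_.adam_step(grads, self.learning_rate)
            self.loss_curve_.append(float(loss))
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = self._as_batch(X)
        return CNNLw.softmax(self.net_.forward(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def predict_patch(self, patch: np.ndarray) -> tuple[str, float]:
        probs = self.predict_proba(patch)[0]
        i = int(probs.argmax())
        return str(self.classes_[i]), float(probs[i])

    def save(self, path: str | Path) -> None:
        self.net_.save(path)
        np.save(str(path) + ".classes.npy", self.classes_)

    @classmethod
    def load(cls, path: str | Path) -> "CNNPatchClassifier":
        est = cls()
        est.net_ = CNNLw.load(path)
        est.classes_ = np.load(str(path) + ".classes.npy", allow_pickle=True)
        est.patch_side = est.net_.spec.input_side
        return est


def build_cnn_lw(num_classes: int, spec: CnnLwSpec | None = None, **kwargs) -> CNNPatchClassifier:
    """Construct an (untrained) lightweight CNN classifier."""
    spec = spec or CnnLwSpec()
    spec.spatial_ladder()
    return CNNPatchClassifier(patch_side=spec.input_side, **kwargs)
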