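"""Convolutional inference network and curve-difference loss.

The network maps a standardized 4 x W encoded tree, together with three
standardized non-sigmoid scalars (carrying capacity, initial population,
functional death rate), to either the four sigmoid response parameters
("sigmoid" head) or the response value in discrete affinity bins ("per-bin"
head).  Architecture: three 1-D convolutions (25/25/40 filters, kernel 4,
valid padding) with a 2/2 max pool after the second, global average
pooling, then dense layers 48-32-16-8 with the non-sigmoid scalars
concatenated before the first dense layer; ELU activations in hidden
layers, linear output passed through a clip to fixed per-parameter bounds.

Training minimizes the curve-difference loss: the area between the true and
predicted response curves divided by the area under the true curve on the
affinity domain [-2.5, 3].  This is a scaled L1 distance between curve
shapes; it is preferred over parameter-space MSE because widely separated
parameter sets can produce nearly identical sigmoids.

The network, backpropagation, Adam optimizer and exponential-moving-average
(EMA) weight tracking are implemented directly on NumPy arrays; the model
is small (~10k parameters) and trains on one CPU in minutes.  The output
clip uses a straight-through gradient so an output that starts outside its
box is not permanently frozen there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import math
import numpy as np
import yaml

from .encoding import DEFAULT_WIDTH, EncodedTree, InputScaler
from .response import ParamBounds, SigmoidParams

__all__ = [
    "AFFINITY_DOMAIN",
    "affinity_grid",
    "curve_from_params",
    "curve_difference_loss",
    "NetworkSpec",
    "TrainConfig",
    "ResponseNet",
    "build_network",
    "train",
    "TrainedModel",
]

AFFINITY_DOMAIN = (-2.5, 3.0)


def affinity_grid(n: int = 111) -> np.ndarray:
    """Affinity grid over the loss domain [-2.5, 3]."""
    return np.linspace(*AFFINITY_DOMAIN, n)


def curve_from_params(params: np.ndarray | SigmoidParams, grid: np.ndarray) -> np.ndarray:
    """Sigmoid response curve(s) on a grid; accepts (4,) or (n, 4) arrays."""
    if isinstance(params, SigmoidParams):
        params = params.as_array()
    arr = np.asarray(params, dtype=float)
    p = np.atleast_2d(arr)
    x_c, x_h, y_c, y_h = (p[:, i : i + 1] for i in range(4))
    z = np.clip(-x_c * (grid[None, :] - x_h), -700, 700)
    curves = y_c / (1.0 + np.exp(z)) + y_h
    return curves[0] if arr.ndim == 1 else curves


def curve_difference_loss(
    true_curve: np.ndarray, inferred_curve: np.ndarray, grid: np.ndarray | None = None
) -> float:
    """Area between curves divided by area under the true curve (trapezoid).

    Both curves must share the grid; defaults to the uniform affinity grid
    over the domain with the curves' length.
    """
    true_curve = np.asarray(true_curve, dtype=float)
    inferred_curve = np.asarray(inferred_curve, dtype=float)
    if grid is None:
        grid = np.linspace(*AFFINITY_DOMAIN, len(true_curve))
    if true_curve.shape != inferred_curve.shape or true_curve.shape != grid.shape:
        raise ValueError("curves and grid must share one shape")
    denom = float(np.trapezoid(true_curve, grid))
    if denom <= 0:
        raise ValueError("zero area under the true curve")
    return float(np.trapezoid(np.abs(true_curve - inferred_curve), grid)) / denom


def _trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    w = np.zeros_like(grid)
    d = np.diff(grid)
    w[:-1] += d / 2
    w[1:] += d / 2
    return w


# ---------------------------------------------------------------------------
# Architecture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkSpec:
    """Layer plan of the inference network."""

    width: int = DEFAULT_WIDTH
    in_channels: int = 4
    conv_filters: tuple[int, int, int] = (25, 25, 40)
    kernel_size: int = 4
    pool_size: int = 2
    dense_units: tuple[int, ...] = (48, 32, 16, 8)
    n_nonsigmoid: int = 3
    head: str = "sigmoid"  # or "per_bin"
    n_bins: int = 11
    bounds: ParamBounds = field(default_factory=ParamBounds)

    def __post_init__(self) -> None:
        if self.head not in ("sigmoid", "per_bin"):
            raise ValueError(f"unknown head {self.head!r}")

    @property
    def n_outputs(self) -> int:
        return 4 if self.head == "sigmoid" else self.n_bins

    def output_clip(self) -> tuple[np.ndarray, np.ndarray]:
        if self.head == "sigmoid":
            c = self.bounds.clip
            lo = np.array([c[k][0] for k in ("x_c", "x_h", "y_c", "y_h")])
            hi = np.array([c[k][1] for k in ("x_c", "x_h", "y_c", "y_h")])
        else:
            hi_rate = self.bounds.clip["y_c"][1] + self.bounds.clip["y_h"][1]
            lo = np.zeros(self.n_bins)
            hi = np.full(self.n_bins, hi_rate)
        return lo, hi

    def bin_grid(self) -> np.ndarray:
        """Bin-center affinity grid used by the per-bin head."""
        edges = np.linspace(*AFFINITY_DOMAIN, self.n_bins + 1)
        return (edges[:-1] + edges[1:]) / 2


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol (Adam with EMA weight averaging)."""

    learning_rate: float = 0.01
    ema_momentum: float = 0.99
    batch_size: int = 32
    epochs: int = 35
    test_fraction: float = 0.2
    val_fraction: float = 0.1
    clip_grad_norm: float = 1.0  # global gradient-norm clip; None disables
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.test_fraction, self.val_fraction):
            if not 0 < f < 1:
                raise ValueError("split fractions must lie in (0, 1)")


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0)))


def _elu_grad(post: np.ndarray) -> np.ndarray:
    # ELU'(x) = 1 for x > 0 else exp(x) = post-activation + 1
    return np.where(post > 0, 1.0, post + 1.0)


def _conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    # x (B,C,W), w (F,C,K) -> (B,F,W-K+1)
    win = np.lib.stride_tricks.sliding_window_view(x, w.shape[2], axis=2)
    return np.einsum("bcwk,fck->bfw", win, w, optimize=True) + b[None, :, None]


def _conv1d_backward(x: np.ndarray, w: np.ndarray, dy: np.ndarray):
    k = w.shape[2]
    win = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)
    dw = np.einsum("bfw,bcwk->fck", dy, win, optimize=True)
    db = dy.sum(axis=(0, 2))
    pad = np.pad(dy, ((0, 0), (0, 0), (k - 1, k - 1)))
    pwin = np.lib.stride_tricks.sliding_window_view(pad, k, axis=2)
    dx = np.einsum("bfwk,fck->bcw", pwin, w[:, :, ::-1], optimize=True)
    return dx, dw, db


class ResponseNet:
    """The convolutional inference network (NumPy parameters, manual autodiff)."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator) -> None:
        self.spec = spec
        k = spec.kernel_size
        f1, f2, f3 = spec.conv_filters

        def he(*shape):
            fan_in = int(np.prod(shape[:-1])) if len(shape) == 2 else int(np.prod(shape[1:]))
            return rng.standard_normal(shape) * np.sqrt(1.0 / fan_in)

        self.params: dict[str, np.ndarray] = {
            "conv1_w": he(f1, spec.in_channels, k),
            "conv1_b": np.zeros(f1),
            "conv2_w": he(f2, f1, k),
            "conv2_b": np.zeros(f2),
            "conv3_w": he(f3, f2, k),
            "conv3_b": np.zeros(f3),
        }
        sizes = [f3 + spec.n_nonsigmoid, *spec.dense_units, spec.n_outputs]
        for i, (nin, nout) in enumerate(zip(sizes, sizes[1:]), start=1):
            self.params[f"dense{i}_w"] = he(nin, nout)
            self.params[f"dense{i}_b"] = np.zeros(nout)
        # Start the output at the middle of the clip box.
        lo, hi = spec.output_clip()
        self.params[f"dense{len(sizes) - 1}_b"][:] = (lo + hi) / 2
        self._n_dense = len(sizes) - 1

    # -- introspection ------------------------------------------------------

    def layer_param_counts(self) -> dict[str, int]:
        """Trainable parameter counts per layer (weights + bias)."""
        out: dict[str, int] = {}
        for i in (1, 2, 3):
            out[f"conv{i}"] = self.params[f"conv{i}_w"].size + self.params[f"conv{i}_b"].size
        for i in range(1, self._n_dense + 1):
            out[f"dense{i}"] = (
                self.params[f"dense{i}_w"].size + self.params[f"dense{i}_b"].size
            )
        return out

    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())

    # -- forward / backward -------------------------------------------------

    def forward(self, X: np.ndarray, Z: np.ndarray, cache: dict | None = None) -> np.ndarray:
        """Clipped outputs for standardized inputs X (B,4,W) and Z (B,k)."""
        p = self.params
        pool = self.spec.pool_size
        c1 = _elu(_conv1d_forward(X, p["conv1_w"], p["conv1_b"]))
        c2 = _elu(_conv1d_forward(c1, p["conv2_w"], p["conv2_b"]))
        wpool = (c2.shape[2] // pool) * pool
        blocks = c2[:, :, :wpool].reshape(c2.shape[0], c2.shape[1], -1, pool)
        arg = blocks.argmax(axis=3)
        pooled = np.take_along_axis(blocks, arg[..., None], axis=3)[..., 0]
        c3 = _elu(_conv1d_forward(pooled, p["conv3_w"], p["conv3_b"]))
        gap = c3.mean(axis=2)
        hs = [np.concatenate([gap, Z], axis=1)]
        for i in range(1, self._n_dense + 1):
            s = hs[-1] @ p[f"dense{i}_w"] + p[f"dense{i}_b"]
            hs.append(_elu(s) if i < self._n_dense else s)
        lo, hi = self.spec.output_clip()
        out = np.clip(hs[-1], lo, hi)
        if cache is not None:
            cache.update(X=X, c1=c1, c2=c2, wpool=wpool, arg=arg, pooled=pooled,
                         c3=c3, hs=hs)
        return out

    def backward(self, cache: dict, dout: np.ndarray) -> dict[str, np.ndarray]:
        """Parameter gradients given the loss gradient at the (clipped) output.

        The clip is straight-through, so ``dout`` passes unchanged into the
        final dense layer.
        """
        p = self.params
        g: dict[str, np.ndarray] = {}
        hs = cache["hs"]
        ds = dout
        for i in range(self._n_dense, 0, -1):
            g[f"dense{i}_w"] = hs[i - 1].T @ ds
            g[f"dense{i}_b"] = ds.sum(axis=0)
            dh = ds @ p[f"dense{i}_w"].T
            if i > 1:
                ds = dh * _elu_grad(hs[i - 1])
        f3 = self.spec.conv_filters[2]
        dgap = dh[:, :f3]  # gradient w.r.t. the pooled features; Z part ends here
        c3 = cache["c3"]
        dc3 = np.broadcast_to(dgap[:, :, None] / c3.shape[2], c3.shape)
        ds3 = dc3 * _elu_grad(c3)
        dpooled, g["conv3_w"], g["conv3_b"] = _conv1d_backward(
            cache["pooled"], p["conv3_w"], ds3
        )
        c2 = cache["c2"]
        dc2 = np.zeros_like(c2)
        pool = self.spec.pool_size
        wpool = cache["wpool"]
        dblocks = np.zeros((c2.shape[0], c2.shape[1], wpool // pool, pool))
        np.put_along_axis(dblocks, cache["arg"][..., None], dpooled[..., None], axis=3)
        dc2[:, :, :wpool] = dblocks.reshape(c2.shape[0], c2.shape[1], wpool)
        ds2 = dc2 * _elu_grad(c2)
        dc1, g["conv2_w"], g["conv2_b"] = _conv1d_backward(cache["c1"], p["conv2_w"], ds2)
        ds1 = dc1 * _elu_grad(cache["c1"])
        _, g["conv1_w"], g["conv1_b"] = _conv1d_backward(cache["X"], p["conv1_w"], ds1)
        return g

    def predict(self, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
        X = X[None] if X.ndim == 2 else X
        Z = np.atleast_2d(Z)
        return self.forward(X, Z)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        np.savez(path, **self.params)

    def load_params(self, path: str | Path) -> None:
        with np.load(path) as data:
            for k in self.params:
                self.params[k] = data[k]


def build_network(spec: NetworkSpec, seed: int = 0) -> ResponseNet:
    """Construct an initialized network from a layer plan."""
    return ResponseNet(spec, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# Loss gradients
# ---------------------------------------------------------------------------


def _sigmoid_head_loss_grad(
    pred: np.ndarray, truth_params: np.ndarray, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean curve loss over the batch and its gradient w.r.t. predictions."""
    w = _trapezoid_weights(grid)
    true_curves = curve_from_params(truth_params, grid)
    pred_curves = curve_from_params(pred, grid)
    denom = (true_curves * w).sum(axis=1)
    diff = true_curves - pred_curves
    losses = (np.abs(diff) * w).sum(axis=1) / denom
    # d pred_curve / d params
    x_c, x_h, y_c, y_h = (pred[:, i : i + 1] for i in range(4))
    z = np.clip(-x_c * (grid[None, :] - x_h), -700, 700)
    s = 1.0 / (1.0 + np.exp(z))
    sp = s * (1.0 - s)
    dc = np.stack(
        [
            y_c * sp * (grid[None, :] - x_h),
            -y_c * sp * x_c,
            s,
            np.ones_like(s),
        ],
        axis=2,
    )  # (B, G, 4)
    dl_dc = -np.sign(diff) * w / denom[:, None]  # (B, G)
    grad = np.einsum("bg,bgp->bp", dl_dc, dc) / len(pred)
    return losses, grad


def _per_bin_loss_grad(
    pred: np.ndarray, truth_params: np.ndarray, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    w = _trapezoid_weights(grid)
    true_curves = curve_from_params(truth_params, grid)
    denom = (true_curves * w).sum(axis=1)
    diff = true_curves - pred
    losses = (np.abs(diff) * w).sum(axis=1) / denom
    grad = (-np.sign(diff) * w / denom[:, None]) / len(pred)
    return losses, grad


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(
        self, params: dict[str, np.ndarray], lr: float, clip_norm: float | None = None
    ) -> None:
        self.lr = lr
        self.clip_norm = clip_norm
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-7
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        if self.clip_norm is not None:
            # global norm clip: a single outlier batch cannot knock the ELU
            # stack into its saturated (dead) regime
            norm = math.sqrt(sum(float((g * g).sum()) for g in grads.values()))
            if norm > self.clip_norm:
                scale = self.clip_norm / norm
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for k, gk in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk * gk
            params[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    test_loss: float | None = None


def _split_indices(n: int, cfg: TrainConfig, rng: np.random.Generator):
    order = rng.permutation(n)
    n_test = int(round(cfg.test_fraction * n))
    test = order[:n_test]
    rest = order[n_test:]
    n_val = int(round(cfg.val_fraction * len(rest)))
    return rest[n_val:], rest[:n_val], test


def train(
    net: ResponseNet,
    X: np.ndarray,
    Z: np.ndarray,
    truth_params: np.ndarray,
    cfg: TrainConfig,
) -> TrainHistory:
    """Train the network with Adam + EMA on standardized inputs.

    ``truth_params`` holds each tree's true sigmoid parameters (n, 4); the
    loss is always the curve difference between the truth curve and the
    predicted curve (at bin resolution for the per-bin head).  The final
    network weights are the EMA shadow weights.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = affinity_grid() if net.spec.head == "sigmoid" else net.spec.bin_grid()
    loss_grad = (
        _sigmoid_head_loss_grad if net.spec.head == "sigmoid" else _per_bin_loss_grad
    )
    tr, va, te = _split_indices(len(X), cfg, rng)
    opt = _Adam(net.params, cfg.learning_rate, cfg.clip_grad_norm)
    ema = {k: v.copy() for k, v in net.params.items()}
    hist = TrainHistory()

    def eval_loss(idx: np.ndarray, params: dict[str, np.ndarray]) -> float:
        saved = net.params
        net.params = params
        losses = []
        for start in range(0, len(idx), 256):
            b = idx[start : start + 256]
            out = net.forward(X[b], Z[b])
            ls, _ = loss_grad(out, truth_params[b], grid)
            losses.append(ls)
        net.params = saved
        return float(np.concatenate(losses).mean())

    for epoch in range(cfg.epochs):
        order = rng.permutation(tr)
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            b = order[start : start + cfg.batch_size]
            cache: dict = {}
            out = net.forward(X[b], Z[b], cache)
            losses, dout = loss_grad(out, truth_params[b], grid)
            if not np.all(np.isfinite(losses)):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}: "
                    f"{losses}"
                )
            epoch_losses.append(losses.mean())
            grads = net.backward(cache, dout)
            opt.step(net.params, grads)
            mom = cfg.ema_momentum
            for k, v in net.params.items():
                ema[k] = mom * ema[k] + (1 - mom) * v
        hist.train_loss.append(float(np.mean(epoch_losses)))
        hist.val_loss.append(eval_loss(va, ema) if len(va) else float("nan"))
    net.params = ema
    hist.test_loss = eval_loss(te, net.params) if len(te) else None
    return hist


# ---------------------------------------------------------------------------
# Bundled trained model
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """A trained network bundled with its input scaler and history.

    Predictions must go through the training scaler; this container owns it
    and refuses raw (unscaled) prediction.
    """

    net: ResponseNet
    scaler: InputScaler
    history: TrainHistory

    def predict_params(
        self, encoded: list[EncodedTree], nonsigmoid: np.ndarray
    ) -> np.ndarray:
        """Clipped head outputs for encoded trees and raw non-sigmoid values.

        ``nonsigmoid`` is (n, k) or (k,) broadcast to all trees; values are
        in natural units and standardized internally.
        """
        if self.scaler is None:
            raise ValueError(
                "no input scaler attached: inputs cannot be standardized"
            )
        ns = np.atleast_2d(np.asarray(nonsigmoid, dtype=float))
        if len(ns) == 1:
            ns = np.repeat(ns, len(encoded), axis=0)
        X, Z = self.scaler.transform(encoded, ns)
        return self.net.forward(X, Z)

    def predict_curves(
        self, encoded: list[EncodedTree], nonsigmoid: np.ndarray, grid: np.ndarray
    ) -> np.ndarray:
        out = self.predict_params(encoded, nonsigmoid)
        if self.net.spec.head == "sigmoid":
            return curve_from_params(out, grid)
        # per-bin: interpolate bin values onto the requested grid
        bins = self.net.spec.bin_grid()
        return np.stack([np.interp(grid, bins, row) for row in out])

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.net.save(directory / "weights.npz")
        self.scaler.to_yaml(directory / "scaler.yaml")
        spec = self.net.spec
        meta = {
            "head": spec.head,
            "width": spec.width,
            "n_bins": spec.n_bins,
            "history": {
                "train_loss": self.history.train_loss,
                "val_loss": self.history.val_loss,
                "test_loss": self.history.test_loss,
            },
        }
        (directory / "model.yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        meta = yaml.safe_load((directory / "model.yaml").read_text())
        spec = NetworkSpec(head=meta["head"], width=meta["width"], n_bins=meta["n_bins"])
        net = build_network(spec)
        net.load_params(directory / "weights.npz")
        scaler = InputScaler.from_yaml(directory / "scaler.yaml")
        h = meta.get("history", {})
        hist = TrainHistory(
            train_loss=h.get("train_loss", []),
            val_loss=h.get("val_loss", []),
            test_loss=h.get("test_loss"),
        )
        return cls(net=net, scaler=scaler, history=hist)
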