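"""Sigmoid affinity-fitness response function and constrained parameter sampling.

The affinity of a B cell receptor is expressed on a log10 scale relative to
the naive dissociation constant,

    x = -log10(K_D / K_D^naive),

so the naive sequence has affinity 0 and larger ``x`` means stronger binding.
The birth (division) rate of a cell with affinity ``x`` is modeled as a
four-parameter sigmoid

    lambda(x) = y_c / (1 + exp(-x_c (x - x_h))) + y_h

with steepness ``x_c`` (``xscale``), midpoint ``x_h`` (``xshift``), scale
``y_c`` (``yscale``, the dynamic range between the asymptotes) and lower
asymptote ``y_h`` (``yshift``), all rates in births per day.

Training-set parameters are drawn from per-parameter boxes subject to an
additional constraint on the naive (zero-affinity) birth rate

    lambda_0 = y_c / (1 + exp(x_c x_h))

which must land in a configured interval; without it, independently drawn
boxes produce unrealistically fast or slow founder populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SigmoidParams",
    "ParamBounds",
    "CENTRAL_MIMIC_PARAMS",
    "sigmoid_response",
    "response_curve",
    "naive_birth_rate",
    "affinity_from_kd",
    "kd_ratio_from_affinity",
    "sample_sigmoid_params",
    "clip_params",
]

Interval = tuple[float, float]


@dataclass(frozen=True)
class SigmoidParams:
    """The four sigmoid response parameters (xscale, xshift, yscale, yshift)."""

    x_c: float
    x_h: float
    y_c: float
    y_h: float

    def __post_init__(self) -> None:
        vals = (self.x_c, self.x_h, self.y_c, self.y_h)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"sigmoid parameters must be finite, got {vals}")
        if self.y_c <= 0:
            raise ValueError(f"y_c must be > 0, got {self.y_c}")
        if self.y_h < 0:
            raise ValueError(f"y_h must be >= 0, got {self.y_h}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x_c, self.x_h, self.y_c, self.y_h], dtype=float)

    @classmethod
    def from_array(cls, a) -> "SigmoidParams":
        return cls(*(float(v) for v in a))


#: Sigmoid parameters of the "central data mimic" configuration.
CENTRAL_MIMIC_PARAMS = SigmoidParams(x_c=1.6, x_h=2.0, y_c=18.2, y_h=0.4)


def _default_box() -> dict[str, Interval]:
    # Training-sample simulation boxes.
    return {"x_c": (0.01, 2.0), "x_h": (-0.5, 3.0), "y_c": (0.5, 35.0), "y_h": (0.0, 0.6)}


def _default_clip() -> dict[str, Interval]:
    # Network clip-function boxes: wider than the simulation boxes.
    return {"x_c": (0.001, 3.5), "x_h": (-1.5, 5.0), "y_c": (0.1, 65.0), "y_h": (0.0, 10.0)}


@dataclass(frozen=True)
class ParamBounds:
    """Per-parameter intervals, the naive-birth-rate interval, and clip boxes."""

    box: dict[str, Interval] = field(default_factory=_default_box)
    lambda0: Interval = (0.1, 15.0)
    clip: dict[str, Interval] = field(default_factory=_default_clip)

    def __post_init__(self) -> None:
        for name, (lo, hi) in {**self.box, **self.clip, "lambda0": self.lambda0}.items():
            if lo > hi:
                raise ValueError(f"bounds for {name} inverted: [{lo}, {hi}]")

    def with_box(self, **kw: Interval) -> "ParamBounds":
        return replace(self, box={**self.box, **kw})

    # -- YAML persistence (simulation boxes + clip boxes) -------------------

    def to_yaml(self, path) -> None:
        import yaml

        payload = {
            "box": {k: list(v) for k, v in self.box.items()},
            "lambda0": list(self.lambda0),
            "clip": {k: list(v) for k, v in self.clip.items()},
        }
        from pathlib import Path

        Path(path).write_text(yaml.safe_dump(payload))

    @classmethod
    def from_yaml(cls, path) -> "ParamBounds":
        import yaml
        from pathlib import Path

        d = yaml.safe_load(Path(path).read_text())
        return cls(
            box={k: tuple(v) for k, v in d["box"].items()},
            lambda0=tuple(d["lambda0"]),
            clip={k: tuple(v) for k, v in d["clip"].items()},
        )


def sigmoid_response(params: SigmoidParams, x) -> np.ndarray | float:
    """Birth rate lambda(x) of the sigmoid response at affinity ``x``.

    Accepts scalars or arrays.  The exponential is evaluated in a clipped
    form so that extreme affinities return the appropriate asymptote
    instead of overflowing.
    """
    x = np.asarray(x, dtype=float)
    z = np.clip(-params.x_c * (x - params.x_h), -700.0, 700.0)
    out = params.y_c / (1.0 + np.exp(z)) + params.y_h
    return float(out) if out.ndim == 0 else out


def response_curve(params: SigmoidParams, grid: np.ndarray) -> np.ndarray:
    """Sigmoid response evaluated on an affinity grid (vector of rates)."""
    return np.asarray(sigmoid_response(params, grid), dtype=float)


def naive_birth_rate(params: SigmoidParams) -> float:
    """Naive (zero-affinity) birth rate lambda_0 = y_c / (1 + e^{x_c x_h}).

    The lower asymptote ``y_h`` is deliberately neglected, so this equals
    ``sigmoid_response(params, 0) - y_h`` exactly.
    """
    z = min(params.x_c * params.x_h, 700.0)
    return params.y_c / (1.0 + math.exp(z))


def affinity_from_kd(k_d: float, k_d_naive: float) -> float:
    """Affinity x = -log10(K_D / K_D^naive) from dissociation constants (molar)."""
    if k_d <= 0 or k_d_naive <= 0:
        raise ValueError("dissociation constants must be positive")
    return -math.log10(k_d / k_d_naive)


def kd_ratio_from_affinity(x: float) -> float:
    """Inverse of :func:`affinity_from_kd`: K_D / K_D^naive = 10^(-x)."""
    return 10.0 ** (-x)


def _lambda0_xh_interval(x_c: float, bounds: ParamBounds) -> Interval:
    """Admissible x_h interval implied by the naive-birth-rate constraint.

    Solving lambda0 bounds for x_h at fixed x_c gives

        log(y_c^l / lambda0^u - 1) / x_c  <  x_h  <  log(y_c^u / lambda0^l - 1) / x_c.

    A non-positive log argument means the corresponding one-sided constraint
    cannot bind (lambda_0 < y_c always), and it is treated as vacuous.
    """
    yc_l, yc_u = bounds.box["y_c"]
    l0_l, l0_u = bounds.lambda0
    lo = -math.inf
    hi = math.inf
    if x_c > 0:
        arg_lo = yc_l / l0_u - 1.0
        if arg_lo > 0:
            lo = math.log(arg_lo) / x_c
        arg_hi = yc_u / l0_l - 1.0
        if arg_hi > 0:
            hi = math.log(arg_hi) / x_c
    return lo, hi


def sample_sigmoid_params(bounds: ParamBounds, rng: np.random.Generator) -> SigmoidParams:
    """Draw sigmoid parameters uniformly subject to the naive-rate constraint.

    Draw order is x_c, x_h, y_c, y_h.  At each stage the parameter's own box
    is intersected with the interval implied by the naive-birth-rate bounds
    given the parameters already drawn, and the draw is uniform on the
    truncated interval (no rejection loop, so the per-seed draw count is
    reproducible).  y_h is drawn independently in its own box.
    """
    x_c = rng.uniform(*bounds.box["x_c"])

    xh_lo, xh_hi = bounds.box["x_h"]
    c_lo, c_hi = _lambda0_xh_interval(x_c, bounds)
    xh_lo, xh_hi = max(xh_lo, c_lo), min(xh_hi, c_hi)
    if xh_lo > xh_hi:
        raise ValueError(
            f"empty feasible interval for x_h at x_c={x_c:.4g}: [{xh_lo:.4g}, {xh_hi:.4g}]"
        )
    x_h = rng.uniform(xh_lo, xh_hi)

    yc_lo, yc_hi = bounds.box["y_c"]
    denom = 1.0 + math.exp(min(x_c * x_h, 700.0))
    yc_lo = max(yc_lo, bounds.lambda0[0] * denom)
    yc_hi = min(yc_hi, bounds.lambda0[1] * denom)
    if yc_lo > yc_hi:
        raise ValueError(
            f"empty feasible interval for y_c at x_c={x_c:.4g}, x_h={x_h:.4g}"
        )
    y_c = rng.uniform(yc_lo, yc_hi)

    y_h = rng.uniform(*bounds.box["y_h"])
    return SigmoidParams(x_c=x_c, x_h=x_h, y_c=y_c, y_h=y_h)


def clip_params(params: SigmoidParams, bounds: ParamBounds) -> SigmoidParams:
    """Clamp each parameter to its clip box (idempotent)."""
    c = bounds.clip
    return SigmoidParams(
        x_c=min(max(params.x_c, c["x_c"][0]), c["x_c"][1]),
        x_h=min(max(params.x_h, c["x_h"][0]), c["x_h"][1]),
        y_c=min(max(params.y_c, c["y_c"][0]), c["y_c"][1]),
        y_h=min(max(params.y_h, c["y_h"][0]), c["y_h"][1]),
    )
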