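"""5-mer context-dependent somatic hypermutation model.

Each site's mutability depends on the 5-mer centered on it; when a mutation
fires, the site is chosen with probability proportional to its mutability
and the new base from the site's context-specific substitution triple.  A
dimensionless multiplier modulates the total mutation intensity (rate only;
site and base choice are unaffected).  The two terminal positions on each
side of a sequence lack a full 5-mer context and are assigned zero
mutability.

Internally 5-mers are base-4 integer codes (A=0..T=3) so per-site lookups
are table indexing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .affinity import BASES, seq_to_ints

__all__ = [
    "MutabilityModel",
    "site_mutabilities",
    "sequence_mutation_rate",
    "sample_mutation",
    "generate_synthetic_5mer_model",
]

_POW4 = np.array([256, 64, 16, 4, 1], dtype=np.int64)


def _fivemer_codes(ints: np.ndarray) -> np.ndarray:
    """Base-4 codes of all L-4 full 5-mers of an integer sequence."""
    windows = np.lib.stride_tricks.sliding_window_view(ints.astype(np.int64), 5)
    return windows @ _POW4


def code_to_fivemer(code: int) -> str:
    return "".join(BASES[(code >> (2 * k)) & 3] for k in range(4, -1, -1))


@dataclass(frozen=True)
class MutabilityModel:
    """Per-5-mer mutabilities and substitution probabilities.

    ``mutability[code]`` is the per-site rate (per day, before the
    multiplier) for a site whose 5-mer has that code; ``substitution[code]``
    is a probability vector over the four bases with zero weight on the
    central (current) base.
    """

    mutability: np.ndarray  # (1024,) >= 0
    substitution: np.ndarray  # (1024, 4) rows sum to 1, center base weight 0
    multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.mutability.shape != (1024,) or self.substitution.shape != (1024, 4):
            raise ValueError("mutability must be (1024,), substitution (1024, 4)")
        if np.any(self.mutability < 0):
            raise ValueError("mutabilities must be non-negative")
        if not np.allclose(self.substitution.sum(axis=1), 1.0):
            raise ValueError("substitution triples must sum to 1")

    def with_multiplier(self, multiplier: float) -> "MutabilityModel":
        return MutabilityModel(self.mutability, self.substitution, multiplier)

    # -- serialization ------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "fivemer": [code_to_fivemer(c) for c in range(1024)],
                "mutability": self.mutability,
                **{f"p_{b}": self.substitution[:, i] for i, b in enumerate(BASES)},
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, multiplier: float = 1.0) -> "MutabilityModel":
        df = pd.read_csv(path)
        idx = df["fivemer"].map(lambda f: int((seq_to_ints(f).astype(np.int64) @ _POW4)))
        mut = np.zeros(1024)
        sub = np.full((1024, 4), 0.25)
        mut[idx] = df["mutability"].to_numpy()
        sub[idx] = df[[f"p_{b}" for b in BASES]].to_numpy()
        return cls(mutability=mut, substitution=sub, multiplier=multiplier)


def site_mutabilities(model: MutabilityModel, ints: np.ndarray) -> np.ndarray:
    """Per-site mutability array (length L; terminal two sites each side are 0)."""
    L = len(ints)
    out = np.zeros(L)
    if L >= 5:
        out[2 : L - 2] = model.mutability[_fivemer_codes(ints)]
    return out


def sequence_mutation_rate(model: MutabilityModel, seq: str | np.ndarray) -> float:
    """Total mutation rate of a sequence: multiplier x sum of site mutabilities."""
    ints = seq if isinstance(seq, np.ndarray) else seq_to_ints(seq)
    if len(ints) < 5:
        raise ValueError("sequence must have length >= 5")
    return model.multiplier * float(site_mutabilities(model, ints).sum())


def sample_mutation(
    model: MutabilityModel, seq: str | np.ndarray, rng: np.random.Generator
) -> tuple[int, int]:
    """Sample one substitution: (position, new base index).

    The position is drawn proportional to site mutability and the base from
    that site's 5-mer substitution triple.
    """
    ints = seq if isinstance(seq, np.ndarray) else seq_to_ints(seq)
    site_mut = site_mutabilities(model, ints)
    total = site_mut.sum()
    if total <= 0:
        raise ValueError("all-zero mutability: no site can mutate")
    pos = int(np.searchsorted(np.cumsum(site_mut), rng.uniform(0.0, total), side="right"))
    pos = min(pos, len(ints) - 1)
    code = int(ints[pos - 2 : pos + 3].astype(np.int64) @ _POW4)
    probs = model.substitution[code]
    new_base = int(rng.choice(4, p=probs))
    return pos, new_base


def generate_synthetic_5mer_model(
    rng: np.random.Generator,
    hotspot_fraction: float = 0.05,
    multiplier: float = 1.0,
    median_rate: float = 2.5e-4,
    sigma: float = 0.8,
    hotspot_boost: float = 10.0,
) -> MutabilityModel:
    """Generate a synthetic 5-mer mutability/substitution model.

    Stand-in for published SHM context models: mutabilities are log-normal
    around ``median_rate`` (per site per day) with a ``hotspot_fraction``
    subset boosted ``hotspot_boost``-fold, giving the heavy-tailed hotspot
    structure characteristic of real SHM targeting.  Substitution triples
    are Dirichlet-distributed over the three non-central bases.
    Deterministic under the supplied generator.
    """
    mut = median_rate * np.exp(sigma * rng.standard_normal(1024))
    n_hot = int(round(hotspot_fraction * 1024))
    if n_hot > 0:
        hot = rng.choice(1024, size=n_hot, replace=False)
        mut[hot] *= hotspot_boost
    sub = np.zeros((1024, 4))
    centers = (np.arange(1024) >> 4) & 3
    for code in range(1024):
        others = [b for b in range(4) if b != centers[code]]
        sub[code, others] = rng.dirichlet(np.ones(3) * 2.0)
    return MutabilityModel(mutability=mut, substitution=sub, multiplier=multiplier)
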