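"""Additive sequence-to-affinity map and functionality classification.

Affinity effects of single-nucleotide variants are tabulated against the
naive sequence (DMS style) and combined additively for multi-mutant
sequences: no epistasis is modeled.  A sequence is nonfunctional iff its
in-frame translation contains a stop codon; death rates downstream treat
functional and nonfunctional cells as two separate categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BASES",
    "AffinityMap",
    "affinity_of",
    "is_functional",
    "generate_synthetic_dms",
    "seq_to_ints",
    "ints_to_seq",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
STOP_CODONS = ("TAA", "TAG", "TGA")
# Codon integer codes (base-4 on A,C,G,T) of the three stop codons.
_STOP_CODES = frozenset(
    16 * _BASE_INDEX[c[0]] + 4 * _BASE_INDEX[c[1]] + _BASE_INDEX[c[2]] for c in STOP_CODONS
)


def seq_to_ints(seq: str) -> np.ndarray:
    """Encode an ACGT string as an int8 array (0..3)."""
    try:
        return np.array([_BASE_INDEX[b] for b in seq.upper()], dtype=np.int8)
    except KeyError as e:
        raise ValueError(f"unknown base {e.args[0]!r} in sequence") from None


def ints_to_seq(ints: np.ndarray) -> str:
    return "".join(BASES[i] for i in ints)


@dataclass(frozen=True)
class AffinityMap:
    """Additive map from nucleotide sequences to affinity.

    ``effects[i, b]`` is the affinity effect (in affinity units) of carrying
    base ``b`` at position ``i``; the naive base at every position has
    effect 0 by construction.
    """

    naive_seq: str
    effects: np.ndarray  # (L, 4) float, naive entries exactly 0
    frame_offset: int = 0
    naive_ints: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        ints = seq_to_ints(self.naive_seq)
        if self.effects.shape != (len(ints), 4):
            raise ValueError(
                f"effects shape {self.effects.shape} does not match sequence "
                f"length {len(ints)}"
            )
        if np.any(self.effects[np.arange(len(ints)), ints] != 0.0):
            raise ValueError("effect of the naive base must be 0 at every position")
        object.__setattr__(self, "naive_ints", ints)

    def __len__(self) -> int:
        return len(self.naive_seq)

    # -- serialization (CSV of position, alt_base, effect) ------------------

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for pos in range(len(self)):
            for b, base in enumerate(BASES):
                if b != self.naive_ints[pos]:
                    rows.append((pos, base, self.effects[pos, b]))
        pd.DataFrame(rows, columns=["position", "alt_base", "effect"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, naive_seq: str, frame_offset: int = 0) -> "AffinityMap":
        df = pd.read_csv(path)
        effects = np.zeros((len(naive_seq), 4))
        for pos, base, eff in df[["position", "alt_base", "effect"]].itertuples(index=False):
            effects[int(pos), _BASE_INDEX[base]] = float(eff)
        return cls(naive_seq=naive_seq, effects=effects, frame_offset=frame_offset)


def _as_ints(seq: str | np.ndarray) -> np.ndarray:
    return seq if isinstance(seq, np.ndarray) else seq_to_ints(seq)


def affinity_of(amap: AffinityMap, seq: str | np.ndarray) -> float:
    """Affinity of ``seq``: sum of tabulated effects at positions differing from naive."""
    ints = _as_ints(seq)
    if len(ints) != len(amap):
        raise ValueError(f"sequence length {len(ints)} != naive length {len(amap)}")
    return float(amap.effects[np.arange(len(ints)), ints].sum())


def is_functional(amap: AffinityMap, seq: str | np.ndarray) -> bool:
    """True iff the in-frame translation of ``seq`` contains no stop codon.

    Codons are read from ``frame_offset``; a trailing partial codon is
    ignored.
    """
    ints = _as_ints(seq)
    return count_stop_codons(ints, amap.frame_offset) == 0


def count_stop_codons(ints: np.ndarray, frame_offset: int = 0) -> int:
    n_codons = (len(ints) - frame_offset) // 3
    if n_codons <= 0:
        return 0
    codons = ints[frame_offset : frame_offset + 3 * n_codons].reshape(n_codons, 3)
    codes = 16 * codons[:, 0] + 4 * codons[:, 1] + codons[:, 2]
    return int(np.isin(codes, list(_STOP_CODES)).sum())


def generate_synthetic_dms(
    rng: np.random.Generator,
    length: int = 60,
    effect_scale: float = 1.5,
    beneficial_scale: float = 0.6,
    deleterious_fraction: float = 0.75,
    frame_offset: int = 0,
) -> AffinityMap:
    """Generate a synthetic additive DMS-style affinity map.

    Stand-in for a real deep mutational scan: single-nucleotide-variant
    effects are drawn from a two-component exponential mixture, mostly
    deleterious (rate ``1/effect_scale``, negative) with a minority of
    beneficial variants (rate ``1/beneficial_scale``, positive).  With the
    default mix, sequences carrying a handful of mutations (~1% SHM on a
    realistic length) have negative mean affinity with a right tail
    reaching a few affinity units, emulating observed GC affinity ranges.

    The naive sequence is drawn without in-frame stop codons so that the
    founder cell is functional.
    """
    if length < 30 or length % 3 != 0:
        raise ValueError("length must be >= 30 and divisible by 3")
    # Draw a stop-free naive sequence codon by codon.
    while True:
        ints = rng.integers(0, 4, size=length).astype(np.int8)
        if count_stop_codons(ints, frame_offset) == 0:
            break
    signs = np.where(rng.random((length, 4)) < deleterious_fraction, -1.0, 1.0)
    mags = np.where(
        signs < 0,
        rng.exponential(effect_scale, size=(length, 4)),
        rng.exponential(beneficial_scale, size=(length, 4)),
    )
    effects = signs * mags
    effects[np.arange(length), ints] = 0.0
    return AffinityMap(naive_seq=ints_to_seq(ints), effects=effects, frame_offset=frame_offset)
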