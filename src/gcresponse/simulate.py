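"""Cell-based forward birth-death-mutation simulation with carrying capacity.

Each living cell carries a nucleotide sequence; its intrinsic birth rate is
the sigmoid response evaluated at the sequence's affinity, its death rate is
one of two constants (functional vs stop-codon-bearing), and its mutation
rate is the 5-mer SHM model summed over the sequence.  A carrying capacity
``N0`` is enforced by logistically modulating rates through the factor

    m = (sum_i mu_i / sum_i lambda_i) ** (N / N0)

so that the process is critical (mean birth rate equals mean death rate over
living cells) when the population sits at capacity.  Three capacity methods
are supported: ``birth`` multiplies all birth rates by ``m`` (default),
``death`` multiplies all death rates by ``1/m``, and ``hard`` leaves rates
untouched but kills a uniformly random cell whenever a birth pushes the
population above ``N0``.

Waiting times for every cell-event pair are exponential with rate equal to
the (modulated) response value; the minimum fires.  This is simulated with
the equivalent Gillespie direct method: one exponential clock at the total
rate, then a rate-proportional choice of event and cell.

The simulation starts from one naive cell that undergoes instantaneous
binary expansion (no mutation, no time passage) to the configured initial
population, runs to the sampling time ``T``, and then samples cells
uniformly without replacement.  Runs that go extinct or end with fewer than
10 living cells are discarded and retried.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .affinity import AffinityMap, count_stop_codons
from .response import SigmoidParams
from .shm import MutabilityModel, site_mutabilities

__all__ = [
    "SimConfig",
    "CENTRAL_MIMIC_CONFIG",
    "GCTree",
    "SimulationFailure",
    "modulation_factor",
    "apply_capacity_method",
    "effective_birth_rate",
    "initial_expansion",
    "run_simulation",
]

# Node end reasons.
ALIVE, DIVIDED, DIED, MUTATED, KILLED = range(5)
_REASON_NAMES = ["alive", "birth", "death", "mutation", "killed"]

CAPACITY_METHODS = ("birth", "death", "hard")


class SimulationFailure(RuntimeError):
    """Raised when every allowed simulation attempt was discarded."""


@dataclass(frozen=True)
class SimConfig:
    """Non-sigmoid simulation parameters.

    Times are in days and rates per day.  ``n_sample`` may be an int or an
    inclusive ``(lo, hi)`` range from which the per-GC sample size is drawn
    uniformly.
    """

    carrying_capacity: int = 500
    capacity_method: str = "birth"
    time_to_sampling: float = 20.0
    n_sample: int | tuple[int, int] = (60, 95)
    initial_population: int = 128
    death_rate_functional: float = 0.2
    death_rate_stop: float = 10.0
    mutability_multiplier: float = 0.5
    min_living_at_sampling: int = 10
    max_retries: int = 20
    keep_full_tree: bool = False

    def __post_init__(self) -> None:
        if self.capacity_method not in CAPACITY_METHODS:
            raise ValueError(
                f"unknown capacity method {self.capacity_method!r}; "
                f"expected one of {CAPACITY_METHODS}"
            )
        if self.death_rate_functional <= 0:
            raise ValueError("functional death rate must be > 0")
        if self.time_to_sampling <= 0:
            raise ValueError("time to sampling must be > 0")
        if self.initial_population < 1:
            raise ValueError("initial population must be >= 1")

    def draw_sample_size(self, rng: np.random.Generator) -> int:
        if isinstance(self.n_sample, tuple):
            lo, hi = self.n_sample
            return int(rng.integers(lo, hi + 1))
        return int(self.n_sample)

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)


#: The "central data mimic" simulation configuration.
CENTRAL_MIMIC_CONFIG = SimConfig()


@dataclass
class GCTree:
    """Full genealogy of one simulated germinal center.

    Flat node-table representation: node 0 is the naive root; every node
    records its parent, birth/end times, affinity, stop-codon count and the
    reason its segment ended (division, death, mutation, hard-capacity kill,
    or alive at sampling).  ``seq_index`` maps nodes to entries of ``seqs``
    (children of a division share their parent's sequence object).
    """

    params: SigmoidParams
    config: SimConfig
    parent: np.ndarray  # (n,) int32, -1 for root
    t_birth: np.ndarray  # (n,) float
    t_end: np.ndarray  # (n,) float
    end_reason: np.ndarray  # (n,) int8
    affinity: np.ndarray  # (n,) float
    n_stops: np.ndarray  # (n,) int16
    seq_index: np.ndarray  # (n,) int32
    seqs: list[np.ndarray]
    sampled: np.ndarray  # (n,) bool
    n_attempts: int = 1
    population_trace: np.ndarray | None = None  # (k, 2) [time, n_living]

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def sampled_ids(self) -> np.ndarray:
        return np.flatnonzero(self.sampled)

    def node_seq(self, node: int) -> np.ndarray:
        return self.seqs[self.seq_index[node]]

    def functional(self, node: int) -> bool:
        return self.n_stops[node] == 0

    def children_of(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for node, par in enumerate(self.parent):
            if par >= 0:
                kids[par].append(node)
        return kids

    def event_log(self) -> pd.DataFrame:
        """Per-node event table (CSV-friendly)."""
        return pd.DataFrame(
            {
                "node": np.arange(self.n_nodes),
                "parent": self.parent,
                "t_birth": self.t_birth,
                "t_end": self.t_end,
                "end_reason": [_REASON_NAMES[r] for r in self.end_reason],
                "affinity": self.affinity,
                "functional": self.n_stops == 0,
                "sampled": self.sampled,
            }
        )

    def write_event_log(self, path: str | Path) -> None:
        self.event_log().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Rates and capacity modulation
# ---------------------------------------------------------------------------


def _scalar_response(params: SigmoidParams, x: float) -> float:
    z = -params.x_c * (x - params.x_h)
    if z > 700.0:
        z = 700.0
    elif z < -700.0:
        z = -700.0
    return params.y_c / (1.0 + math.exp(z)) + params.y_h


def modulation_factor(sum_lam: float, sum_mu: float, n: int, n0: float) -> float:
    """Capacity modulation m = (sum mu / sum lambda)^(N/N0)."""
    if sum_lam <= 0 or sum_mu <= 0:
        raise ValueError(
            f"modulation factor undefined: sum(lambda)={sum_lam}, sum(mu)={sum_mu}"
        )
    z = (n / n0) * math.log(sum_mu / sum_lam)
    return math.exp(min(max(z, -700.0), 700.0))


def apply_capacity_method(
    method: str, lam: np.ndarray, mu: np.ndarray, n0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rate adjustment for a living population under the given capacity method.

    Returns the (birth, death) rate vectors actually used for event timing.
    The ``hard`` method leaves rates untouched (its capacity action is the
    post-birth random kill, applied in the event loop).
    """
    if method not in CAPACITY_METHODS:
        raise ValueError(f"unknown capacity method {method!r}")
    if method == "hard":
        return lam, mu
    m = modulation_factor(float(lam.sum()), float(mu.sum()), len(lam), n0)
    if method == "birth":
        return lam * m, mu
    return lam, mu / m


def effective_birth_rate(
    lam_i: float, mu_i: float, sum_lam: float, sum_mu: float, n: int, n0: float
) -> float:
    """Effective birth rate m*lambda_i - mu_i of one cell in a living population."""
    m = modulation_factor(sum_lam, sum_mu, n, n0)
    return m * lam_i - mu_i


# ---------------------------------------------------------------------------
# Event loop
# ---------------------------------------------------------------------------


class _NodeTable:
    """Append-only node storage used while simulating."""

    def __init__(self) -> None:
        self.parent: list[int] = []
        self.t_birth: list[float] = []
        self.t_end: list[float] = []
        self.end_reason: list[int] = []
        self.affinity: list[float] = []
        self.n_stops: list[int] = []
        self.seq_index: list[int] = []

    def add(self, parent: int, t: float, affinity: float, n_stops: int, seq_idx: int) -> int:
        self.parent.append(parent)
        self.t_birth.append(t)
        self.t_end.append(math.nan)
        self.end_reason.append(ALIVE)
        self.affinity.append(affinity)
        self.n_stops.append(n_stops)
        self.seq_index.append(seq_idx)
        return len(self.parent) - 1

    def close(self, node: int, t: float, reason: int) -> None:
        self.t_end[node] = t
        self.end_reason[node] = reason


def initial_expansion(nodes: _NodeTable, n0: int) -> list[int]:
    """Instantaneous binary expansion of the root to ``n0`` naive cells.

    Splits proceed breadth-first with zero branch lengths and no mutation;
    for non-power-of-two targets the last level is truncated once ``n0``
    leaves exist.  Returns the node ids of the founder cells.
    """
    leaves = [0]
    head = 0
    while len(leaves) - head < n0:
        node = leaves[head]
        head += 1
        nodes.close(node, 0.0, DIVIDED)
        for _ in range(2):
            leaves.append(nodes.add(node, 0.0, nodes.affinity[node], nodes.n_stops[node], nodes.seq_index[node]))
    return leaves[head:]


def _attempt(
    config: SimConfig,
    params: SigmoidParams,
    amap: AffinityMap,
    shm: MutabilityModel,
    rng: np.random.Generator,
    trace: bool,
):
    T = config.time_to_sampling
    n0_cap = float(config.carrying_capacity)
    method = config.capacity_method
    mu_f = config.death_rate_functional
    mu_s = config.death_rate_stop
    mult = config.mutability_multiplier

    nodes = _NodeTable()
    naive = amap.naive_ints
    seqs: list[np.ndarray] = [naive]
    naive_stops = count_stop_codons(naive, amap.frame_offset)
    naive_sitemut = site_mutabilities(shm, naive)
    nodes.add(-1, 0.0, 0.0, naive_stops, 0)
    founder_ids = initial_expansion(nodes, config.initial_population)

    # Living-cell state, compact parallel arrays with swap-remove.
    cap = max(4 * config.carrying_capacity, 256)
    node_id = np.empty(cap, dtype=np.int64)
    lam = np.empty(cap)
    mu = np.empty(cap)
    gam = np.empty(cap)
    sitemuts: list[np.ndarray | None] = [None] * cap

    lam0 = _scalar_response(params, 0.0)
    mu0 = mu_f if naive_stops == 0 else mu_s
    gam0 = mult * float(naive_sitemut.sum())
    n = len(founder_ids)
    node_id[:n] = founder_ids
    lam[:n] = lam0
    mu[:n] = mu0
    gam[:n] = gam0
    for i in range(n):
        sitemuts[i] = naive_sitemut

    sum_lam = n * lam0
    sum_mu = n * mu0
    sum_gam = n * gam0

    t = 0.0
    events_since_refresh = 0
    trace_rows: list[tuple[float, int]] = [(0.0, n)]
    next_trace = 0.25

    def grow() -> None:
        nonlocal cap, node_id, lam, mu, gam, sitemuts
        cap *= 2
        node_id = np.resize(node_id, cap)
        lam = np.resize(lam, cap)
        mu = np.resize(mu, cap)
        gam = np.resize(gam, cap)
        sitemuts = sitemuts + [None] * (cap // 2)

    while n > 0:
        if events_since_refresh >= 4096:
            sum_lam = float(lam[:n].sum())
            sum_mu = float(mu[:n].sum())
            sum_gam = float(gam[:n].sum())
            events_since_refresh = 0

        if method == "birth":
            if sum_lam > 0:
                m = modulation_factor(sum_lam, sum_mu, n, n0_cap)
                birth_tot = m * sum_lam
            else:
                birth_tot = 0.0
            death_tot = sum_mu
        elif method == "death":
            m = modulation_factor(sum_lam, sum_mu, n, n0_cap) if sum_lam > 0 else 1.0
            birth_tot = sum_lam
            death_tot = sum_mu / m
        else:  # hard
            birth_tot = sum_lam
            death_tot = sum_mu

        total = birth_tot + death_tot + sum_gam
        t += rng.exponential(1.0 / total)
        if t >= T:
            break
        events_since_refresh += 1

        u = rng.uniform(0.0, total)
        if u < birth_tot:
            # ---- birth: replace parent by two identical children ----
            i = int(np.searchsorted(np.cumsum(lam[:n]), rng.uniform(0.0, sum_lam)))
            i = min(i, n - 1)
            par = int(node_id[i])
            nodes.close(par, t, DIVIDED)
            if n + 1 >= cap:
                grow()
            # child 1 overwrites slot i; child 2 appended.
            si = nodes.seq_index[par]
            aff = nodes.affinity[par]
            stp = nodes.n_stops[par]
            node_id[i] = nodes.add(par, t, aff, stp, si)
            node_id[n] = nodes.add(par, t, aff, stp, si)
            lam[n] = lam[i]
            mu[n] = mu[i]
            gam[n] = gam[i]
            sitemuts[n] = sitemuts[i]
            n += 1
            sum_lam += lam[i]
            sum_mu += mu[i]
            sum_gam += gam[i]
            if method == "hard" and n > n0_cap:
                j = int(rng.integers(n))
                nodes.close(int(node_id[j]), t, KILLED)
                sum_lam -= lam[j]
                sum_mu -= mu[j]
                sum_gam -= gam[j]
                n -= 1
                if j != n:
                    node_id[j] = node_id[n]
                    lam[j] = lam[n]
                    mu[j] = mu[n]
                    gam[j] = gam[n]
                    sitemuts[j] = sitemuts[n]
        elif u < birth_tot + death_tot:
            # ---- death ----
            i = int(np.searchsorted(np.cumsum(mu[:n]), rng.uniform(0.0, sum_mu)))
            i = min(i, n - 1)
            nodes.close(int(node_id[i]), t, DIED)
            sum_lam -= lam[i]
            sum_mu -= mu[i]
            sum_gam -= gam[i]
            n -= 1
            if i != n:
                node_id[i] = node_id[n]
                lam[i] = lam[n]
                mu[i] = mu[n]
                gam[i] = gam[n]
                sitemuts[i] = sitemuts[n]
        else:
            # ---- mutation: one substitution, cell replaced in place ----
            i = int(np.searchsorted(np.cumsum(gam[:n]), rng.uniform(0.0, sum_gam)))
            i = min(i, n - 1)
            par = int(node_id[i])
            seq = seqs[nodes.seq_index[par]]
            smut = sitemuts[i]
            L = len(seq)
            pos = int(np.searchsorted(np.cumsum(smut), rng.uniform(0.0, smut.sum())))
            pos = min(pos, L - 3)  # terminal sites have zero mutability
            code = int(seq[pos - 2 : pos + 3].astype(np.int64) @ _POW4)
            probs = shm.substitution[code]
            new_base = int(rng.choice(4, p=probs))
            old_base = int(seq[pos])
            new_seq = seq.copy()
            new_seq[pos] = new_base

            new_aff = nodes.affinity[par] - float(amap.effects[pos, old_base]) + float(
                amap.effects[pos, new_base]
            )
            # stop-codon count: only codons overlapping pos can change
            frame = amap.frame_offset
            c0 = (pos - frame) // 3
            lo_c = max(frame + 3 * c0, frame)
            new_stops = (
                nodes.n_stops[par]
                - count_stop_codons(seq[lo_c : lo_c + 3], 0)
                + count_stop_codons(new_seq[lo_c : lo_c + 3], 0)
            )
            # site mutabilities: 5-mers overlapping pos change
            new_smut = smut.copy()
            lo = max(pos - 2, 2)
            hi = min(pos + 2, L - 3)
            for s in range(lo, hi + 1):
                c = int(new_seq[s - 2 : s + 3].astype(np.int64) @ _POW4)
                new_smut[s] = shm.mutability[c]

            nodes.close(par, t, MUTATED)
            seqs.append(new_seq)
            child = nodes.add(par, t, new_aff, new_stops, len(seqs) - 1)

            new_lam = _scalar_response(params, new_aff)
            new_mu = mu_f if new_stops == 0 else mu_s
            new_gam = mult * float(new_smut.sum())
            sum_lam += new_lam - lam[i]
            sum_mu += new_mu - mu[i]
            sum_gam += new_gam - gam[i]
            node_id[i] = child
            lam[i] = new_lam
            mu[i] = new_mu
            gam[i] = new_gam
            sitemuts[i] = new_smut

        if trace and t >= next_trace:
            trace_rows.append((t, n))
            next_trace += 0.25

    if n < config.min_living_at_sampling:
        return None

    # Close all survivors at T and sample uniformly without replacement.
    living = node_id[:n].copy()
    for nd in living:
        nodes.close(int(nd), T, ALIVE)
    k = min(config.draw_sample_size(rng), n)
    chosen = living[rng.choice(n, size=k, replace=False)]

    n_nodes = len(nodes.parent)
    sampled = np.zeros(n_nodes, dtype=bool)
    sampled[chosen] = True
    trace_rows.append((T, n))
    return GCTree(
        params=params,
        config=config,
        parent=np.asarray(nodes.parent, dtype=np.int32),
        t_birth=np.asarray(nodes.t_birth),
        t_end=np.asarray(nodes.t_end),
        end_reason=np.asarray(nodes.end_reason, dtype=np.int8),
        affinity=np.asarray(nodes.affinity),
        n_stops=np.asarray(nodes.n_stops, dtype=np.int16),
        seq_index=np.asarray(nodes.seq_index, dtype=np.int32),
        seqs=seqs,
        sampled=sampled,
        population_trace=np.asarray(trace_rows) if trace else None,
    )


_POW4 = np.array([256, 64, 16, 4, 1], dtype=np.int64)


def run_simulation(
    config: SimConfig,
    params: SigmoidParams,
    amap: AffinityMap,
    shm: MutabilityModel,
    rng: np.random.Generator,
    trace_population: bool = False,
) -> GCTree:
    """Simulate one germinal center, retrying discarded runs.

    A run is discarded if the population goes extinct or holds fewer than
    ``config.min_living_at_sampling`` cells at the sampling time.  Raises
    :class:`SimulationFailure` after ``config.max_retries`` discarded
    attempts.
    """
    shm = shm.with_multiplier(config.mutability_multiplier) if (
        shm.multiplier != config.mutability_multiplier
    ) else shm
    for attempt in range(1, config.max_retries + 1):
        tree = _attempt(config, params, amap, shm, rng, trace_population)
        if tree is not None:
            tree.n_attempts = attempt
            return tree
    raise SimulationFailure(
        f"all {config.max_retries} simulation attempts went extinct or ended "
        f"below {config.min_living_at_sampling} living cells"
    )
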