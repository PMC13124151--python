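"""End-to-end glue: simulate training samples, encode them, fit models.

The training sample spans the plausible parameter space: each GC gets its
own sigmoid parameters (drawn under the naive-birth-rate constraint) and
its own non-sigmoid parameters drawn from configured ranges.  Runs are
desk scale by default - 60 nt sequences and carrying capacities of a few
hundred cells - so a few thousand training trees simulate in well under an
hour on one CPU; the full-scale configuration of the original study is a
parameter choice away (see SimConfig).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .affinity import AffinityMap, generate_synthetic_dms
from .encoding import EncodedTree, encode, ladderize_with_tiebreakers, scale_to_unit_depth, standardize_inputs
from .network import NetworkSpec, TrainConfig, TrainedModel, build_network, train
from .response import ParamBounds, SigmoidParams, sample_sigmoid_params
from .shm import MutabilityModel, generate_synthetic_5mer_model
from .simulate import GCTree, SimConfig, SimulationFailure, run_simulation
from .trees import AnnotatedTree, true_tree_fallback

__all__ = [
    "TrainingSet",
    "DESK_MIMIC_CONFIG",
    "default_fixtures",
    "sample_training_config",
    "encode_annotated",
    "gc_trees_to_encoded",
    "generate_training_set",
    "fit_model",
]


def default_fixtures(
    rng: np.random.Generator, length: int = 60
) -> tuple[AffinityMap, MutabilityModel]:
    """Synthetic DMS affinity map and 5-mer SHM model at default settings."""
    amap = generate_synthetic_dms(rng, length=length)
    shm = generate_synthetic_5mer_model(rng)
    return amap, shm


def sample_training_config(
    rng: np.random.Generator,
    capacity_range: tuple[int, int] = (80, 250),
    init_choices: tuple[int, ...] = (8, 16, 32),
    death_range: tuple[float, float] = (0.05, 0.45),
    time_range: tuple[float, float] = (12.0, 25.0),
    n_sample: tuple[int, int] = (30, 60),
    mutability_multiplier: float = 0.68,
) -> SimConfig:
    """Draw one GC's non-sigmoid simulation configuration for training."""
    return SimConfig(
        carrying_capacity=int(rng.integers(capacity_range[0], capacity_range[1] + 1)),
        initial_population=int(rng.choice(init_choices)),
        death_rate_functional=float(rng.uniform(*death_range)),
        time_to_sampling=float(rng.uniform(*time_range)),
        n_sample=n_sample,
        mutability_multiplier=mutability_multiplier,
        max_retries=10,
    )


def encode_annotated(atree: AnnotatedTree, width: int = 200) -> EncodedTree:
    """Ladderize, scale to unit depth, and encode one annotated tree."""
    ladderize_with_tiebreakers(atree)
    scale_to_unit_depth(atree)
    return encode(atree, width=width)


def gc_trees_to_encoded(
    gc_trees: list[GCTree],
    amap: AffinityMap,
    shm: MutabilityModel,
    width: int = 200,
) -> tuple[list[AnnotatedTree], list[EncodedTree]]:
    annotated = [true_tree_fallback(t, amap, shm) for t in gc_trees]
    return annotated, [encode_annotated(a, width=width) for a in annotated]


@dataclass
class TrainingSet:
    """Encoded training trees with their truth parameters."""

    encoded: list[EncodedTree]
    nonsigmoid: np.ndarray  # (n, 3): capacity, initial population, death rate
    truth_params: np.ndarray  # (n, 4)

    def __len__(self) -> int:
        return len(self.encoded)


def generate_training_set(
    n_trees: int,
    amap: AffinityMap,
    shm: MutabilityModel,
    rng: np.random.Generator,
    bounds: ParamBounds | None = None,
    config_sampler=sample_training_config,
    width: int = 200,
) -> TrainingSet:
    """Simulate and encode a training sample of ``n_trees`` GCs.

    Each tree draws fresh sigmoid parameters (constrained sampling) and a
    fresh non-sigmoid configuration.  Parameter combinations whose
    simulations are discarded repeatedly (extinction-prone corners of the
    box) are redrawn rather than retried forever.
    """
    bounds = bounds or ParamBounds()
    encoded: list[EncodedTree] = []
    nonsigmoid: list[list[float]] = []
    truth: list[np.ndarray] = []
    while len(encoded) < n_trees:
        params = sample_sigmoid_params(bounds, rng)
        config = config_sampler(rng)
        try:
            tree = run_simulation(config, params, amap, shm, rng)
        except SimulationFailure:
            continue
        atree = true_tree_fallback(tree, amap, shm)
        encoded.append(encode_annotated(atree, width=width))
        nonsigmoid.append(
            [config.carrying_capacity, config.initial_population, config.death_rate_functional]
        )
        truth.append(params.as_array())
    return TrainingSet(
        encoded=encoded,
        nonsigmoid=np.asarray(nonsigmoid),
        truth_params=np.stack(truth),
    )


#: Desk-scale data-mimic base configuration: all non-grid settings sit inside
#: the training ranges of :func:`sample_training_config`.
DESK_MIMIC_CONFIG = SimConfig(
    carrying_capacity=200,
    time_to_sampling=20.0,
    n_sample=(30, 60),
    initial_population=32,
    death_rate_functional=0.2,
    mutability_multiplier=0.5,
)


def fit_model(
    training_set: TrainingSet,
    head: str = "sigmoid",
    train_config: TrainConfig | None = None,
    width: int = 200,
    bounds: ParamBounds | None = None,
) -> TrainedModel:
    """Standardize a training set, build the network, and train it."""
    train_config = train_config or TrainConfig()
    X, Z, scaler = standardize_inputs(training_set.encoded, training_set.nonsigmoid)
    spec = NetworkSpec(width=width, head=head, bounds=bounds or ParamBounds())
    net = build_network(spec, seed=train_config.seed)
    history = train(net, X, Z, training_set.truth_params, train_config)
    return TrainedModel(net=net, scaler=scaler, history=history)
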