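"""Automatic grid-size selection for the reference map.

The optimal grid is the one whose neuron prototypes are mutually
non-redundant: no unordered pair of prototypes has Pearson correlation
above the threshold ``theta``. Starting from an initial scalar size

    s = sqrt(n_variables / 2) + 1,

candidate grids are taken at ``d1 = ceil(s - 1)``, ``d2 = floor(s - 1)``;
for each candidate several maps are trained with distinct derived seeds, and
the first map achieving zero redundant pairs accepts the size. Otherwise
``s`` is decremented by one and the search continues; if every candidate
down to ``min_neurons`` is redundant, the smallest candidate is returned
with ``exhausted=True`` (taking its least-redundant map).

The search only shrinks the grid: the initial size intentionally
over-provisions neurons, so a non-redundant map at the starting size is
accepted immediately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_scale import ConditionTable
from .som_engine import GridSize, SOMModel, neuron_correlations, train_som

__all__ = [
    "OptimizerConfig",
    "OptimizerDiagnostics",
    "initial_size",
    "redundant_pair_count",
    "opt_map_size",
    "build_reference_som",
]


@dataclass(frozen=True)
class OptimizerConfig:
    """Settings for the grid search.

    theta
        Redundancy threshold on prototype Pearson correlation, in (0, 1).
    n_maps_per_size
        How many independently seeded maps to train per candidate size.
    seed
        Master seed; all per-map training seeds are derived from it.
    initial_size_override
        Skip the ``sqrt(n/2)+1`` heuristic and start from this scalar.
    min_neurons
        Stop shrinking once a candidate would have fewer neurons than this.
    n_epochs
        Training epochs per candidate map.
    """

    theta: float = 0.9
    n_maps_per_size: int = 5
    seed: int = 0
    initial_size_override: float | None = None
    min_neurons: int = 2
    n_epochs: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must be strictly between 0 and 1")
        if self.n_maps_per_size < 1:
            raise ValueError("n_maps_per_size must be >= 1")
        if self.min_neurons < 1:
            raise ValueError("min_neurons must be >= 1")


@dataclass
class OptimizerDiagnostics:
    """One record per trained candidate map, plus the accepted outcome."""

    records: list[dict] = field(default_factory=list)
    chosen_size: GridSize | None = None
    chosen_seed: int | None = None
    exhausted: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records,
            columns=["d1", "d2", "map_index", "seed", "redundant_pairs", "accepted"],
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def initial_size(n_variables: int, override: float | None = None) -> float:
    """Initial scalar map size: ``sqrt(n/2) + 1`` (minimum 2), or the override."""
    if n_variables < 2:
        raise ValueError("need at least 2 variables to size a map")
    if override is not None:
        if override <= 0:
            raise ValueError("initial size override must be positive")
        return float(override)
    return max(2.0, math.sqrt(n_variables / 2.0) + 1.0)


def redundant_pair_count(model: SOMModel, theta: float) -> int:
    """Number of unordered neuron pairs with prototype correlation > theta.

    Constant (zero-variance) prototypes are never counted as redundant.
    """
    corr = neuron_correlations(model)
    iu = np.triu_indices(corr.n_neurons, k=1)
    return int(np.sum(corr.values[iu] > theta))


def _derived_seed(master: int, size_index: int, map_index: int) -> int:
    ss = np.random.SeedSequence([int(master) % (2**31), size_index, map_index])
    return int(ss.generate_state(1)[0] % (2**31))


def _candidate_sizes(s0: float, min_neurons: int) -> list[GridSize]:
    sizes: list[GridSize] = []
    s = s0
    prev_neurons = None
    while True:
        d1 = math.ceil(s - 1.0)
        d2 = math.floor(s - 1.0)
        if d1 < 1 or d2 < 1 or d1 * d2 < min_neurons or d1 * d2 < 2:
            break
        if prev_neurons is None or d1 * d2 < prev_neurons:
            sizes.append(GridSize(d1, d2))
            prev_neurons = d1 * d2
        s -= 1.0
    return sizes


def opt_map_size(
    data: ConditionTable,
    config: OptimizerConfig | None = None,
) -> tuple[GridSize, OptimizerDiagnostics]:
    """Find the largest candidate grid whose prototypes are non-redundant.

    Deterministic for a fixed ``config.seed``. Returns the accepted grid and
    full per-map diagnostics; the accepted map's training seed is recorded in
    ``diagnostics.chosen_seed`` so the reference map can be rebuilt exactly.
    """
    config = config or OptimizerConfig()
    if data.n_variables < config.min_neurons:
        raise ValueError(
            f"only {data.n_variables} variables but min_neurons={config.min_neurons}; "
            "lower min_neurons"
        )
    s0 = initial_size(data.n_variables, config.initial_size_override)
    sizes = _candidate_sizes(s0, config.min_neurons)
    if not sizes:
        raise ValueError(
            f"no candidate grid with at least {config.min_neurons} neurons "
            f"from initial size {s0}"
        )

    diag = OptimizerDiagnostics()
    fallback: tuple[int, GridSize, int] | None = None  # (count, size, seed)
    for si, size in enumerate(sizes):
        for mi in range(config.n_maps_per_size):
            seed = _derived_seed(config.seed, si, mi)
            model = train_som(data, size, n_epochs=config.n_epochs, seed=seed)
            count = redundant_pair_count(model, config.theta)
            accepted = count == 0
            diag.records.append(
                {"d1": size.d1, "d2": size.d2, "map_index": mi, "seed": seed,
                 "redundant_pairs": count, "accepted": accepted}
            )
            if si == len(sizes) - 1 and (fallback is None or count < fallback[0]):
                fallback = (count, size, seed)
            if accepted:
                diag.chosen_size = size
                diag.chosen_seed = seed
                return size, diag
    # search exhausted: smallest size, least-redundant map
    assert fallback is not None
    diag.exhausted = True
    diag.chosen_size = fallback[1]
    diag.chosen_seed = fallback[2]
    return fallback[1], diag


def build_reference_som(
    data: ConditionTable,
    config: OptimizerConfig | None = None,
) -> tuple[SOMModel, OptimizerDiagnostics]:
    """Run the grid search and train the accepted reference map.

    Retraining with the recorded seed reproduces the accepted map exactly
    (training is deterministic), so the returned model satisfies the
    non-redundancy invariant whenever ``exhausted`` is False.
    """
    config = config or OptimizerConfig()
    size, diag = opt_map_size(data, config)
    model = train_som(data, size, n_epochs=config.n_epochs, seed=diag.chosen_seed)
    return model, diag
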