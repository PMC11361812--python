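"""Batch self-organizing map on a rectangular grid.

The reference map is trained on the scaled control condition only. Test
conditions are later projected onto it by best-matching-unit (BMU) lookup,
so the trainer's contract is: deterministic for a fixed seed (bit-identical
codebooks across runs), prototypes that converge to local cluster means, and
stable 1-based row-major neuron ids.

The update is the classical batch rule: per epoch every data row is assigned
to its BMU, then each neuron's prototype becomes the Gaussian-neighborhood
weighted mean of all rows,

    c_j  <-  sum_i h(j, bmu_i) x_i  /  sum_i h(j, bmu_i),
    h(j, b) = exp(-dist_grid(j, b)^2 / (2 sigma^2)),

with sigma decaying linearly from max(d1, d2)/2 down to a small final value
so that the last epochs act like a seeded k-means refinement. Batch training
is used (rather than the online rule) because its result does not depend on
the presentation order of rows, which makes determinism trivial to guarantee.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_scale import ConditionTable

__all__ = [
    "GridSize",
    "SOMModel",
    "CorrelationMatrix",
    "train_som",
    "best_matching_unit",
    "bmu_indices",
    "neuron_correlations",
    "quantization_error",
]

_SERIAL_VERSION = 1


@dataclass(frozen=True)
class GridSize:
    """Rectangular SOM grid: ``d1`` rows x ``d2`` columns."""

    d1: int
    d2: int

    def __post_init__(self) -> None:
        if self.d1 < 1 or self.d2 < 1:
            raise ValueError(f"grid dimensions must be >= 1, got {self.d1}x{self.d2}")
        if self.d1 * self.d2 < 2:
            raise ValueError("grid must have at least 2 neurons")

    @property
    def n_neurons(self) -> int:
        return self.d1 * self.d2

    def positions(self) -> np.ndarray:
        """(n_neurons, 2) integer (row, col) coordinates, row-major."""
        rows, cols = np.divmod(np.arange(self.n_neurons), self.d2)
        return np.column_stack([rows, cols])


@dataclass
class SOMModel:
    """A trained map.

    Neuron ids are 1-based in row-major order (top-left neuron = 1); this is
    a file-format commitment kept across serialization. ``training_assignments``
    maps every control variable id to the neuron it landed on after the last
    epoch.
    """

    grid: GridSize
    codebook: np.ndarray  # (n_neurons, M)
    measurement_labels: list[str]
    initial_radius: float
    final_radius: float
    n_epochs: int
    seed: int
    neighborhood: str = "gaussian"
    training_assignments: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codebook = np.asarray(self.codebook, dtype=float)
        if self.codebook.shape[0] != self.grid.n_neurons:
            raise ValueError("codebook row count does not match grid size")
        if not np.isfinite(self.codebook).all():
            raise ValueError("codebook contains non-finite values")

    @property
    def n_neurons(self) -> int:
        return self.grid.n_neurons

    @property
    def n_measurements(self) -> int:
        return self.codebook.shape[1]

    def neuron_position(self, neuron_id: int) -> tuple[int, int]:
        """0-based (row, col) grid coordinate of a 1-based neuron id."""
        if not 1 <= neuron_id <= self.n_neurons:
            raise ValueError(f"neuron id {neuron_id} outside 1..{self.n_neurons}")
        return divmod(neuron_id - 1, self.grid.d2)

    def prototype(self, neuron_id: int) -> np.ndarray:
        if not 1 <= neuron_id <= self.n_neurons:
            raise ValueError(f"neuron id {neuron_id} outside 1..{self.n_neurons}")
        return self.codebook[neuron_id - 1]

    # ---- serialization ---------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "format_version": _SERIAL_VERSION,
            "grid": {"d1": self.grid.d1, "d2": self.grid.d2},
            # float hex preserves the codebook bit-exactly through text
            "codebook_hex": [[v.hex() for v in row] for row in self.codebook],
            "codebook": self.codebook.tolist(),
            "measurement_labels": self.measurement_labels,
            "neighborhood": self.neighborhood,
            "initial_radius": self.initial_radius,
            "final_radius": self.final_radius,
            "n_epochs": self.n_epochs,
            "seed": self.seed,
            "training_assignments": self.training_assignments,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SOMModel":
        doc = json.loads(text)
        if doc.get("format_version", 0) > _SERIAL_VERSION:
            warnings.warn("model file written by a newer format version")
        if "codebook_hex" in doc:
            codebook = np.array(
                [[float.fromhex(v) for v in row] for row in doc["codebook_hex"]]
            )
        else:
            codebook = np.array(doc["codebook"], dtype=float)
        return cls(
            grid=GridSize(doc["grid"]["d1"], doc["grid"]["d2"]),
            codebook=codebook,
            measurement_labels=[str(x) for x in doc["measurement_labels"]],
            neighborhood=doc.get("neighborhood", "gaussian"),
            initial_radius=float(doc["initial_radius"]),
            final_radius=float(doc["final_radius"]),
            n_epochs=int(doc["n_epochs"]),
            seed=int(doc["seed"]),
            training_assignments={k: int(v) for k, v in doc["training_assignments"].items()},
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "SOMModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations between codebook rows.

    ``zero_variance`` flags constant prototypes; their correlations with
    everything are recorded as 0 (a constant prototype can never be redundant
    under a correlation threshold), the diagonal stays 1.
    """

    values: np.ndarray
    zero_variance: np.ndarray  # bool per neuron

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]


def bmu_indices(codebook: np.ndarray, data: np.ndarray) -> np.ndarray:
    """0-based BMU index per data row; ties go to the lowest neuron id."""
    # squared Euclidean distances; argmin returns the first (lowest-id) minimum
    d2 = (
        np.sum(data**2, axis=1)[:, None]
        - 2.0 * data @ codebook.T
        + np.sum(codebook**2, axis=1)[None, :]
    )
    return np.argmin(d2, axis=1)


def best_matching_unit(model: SOMModel, profile: np.ndarray) -> int:
    """1-based id of the neuron nearest (Euclidean) to ``profile``.

    Ties are broken toward the lowest neuron id.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or profile.shape[0] != model.n_measurements:
        raise ValueError(
            f"profile must be a vector of length {model.n_measurements}"
        )
    if not np.isfinite(profile).all():
        raise ValueError("profile contains non-finite values")
    # exact distance comparison (no expansion trick) so exact ties stay ties
    d = np.sqrt(np.sum((model.codebook - profile[None, :]) ** 2, axis=1))
    return int(np.argmin(d)) + 1


def _farthest_point_order(grid: GridSize) -> list[int]:
    """Deterministic ordering of neuron indices that spreads over the lattice.

    Starts at the top-left corner, then greedily picks the position whose
    minimum grid distance to the already chosen ones is largest (ties to the
    lowest neuron id).
    """
    pos = grid.positions().astype(float)
    k = grid.n_neurons
    chosen = [0]
    remaining = list(range(1, k))
    while remaining:
        best = max(
            remaining,
            key=lambda j: (
                min(float(np.sum((pos[j] - pos[c]) ** 2)) for c in chosen),
                -j,
            ),
        )
        chosen.append(best)
        remaining.remove(best)
    return chosen


def _initial_codebook(X: np.ndarray, grid: GridSize, rng) -> np.ndarray:
    """Seed the codebook from sampled distinct data rows, spread on the grid.

    Distinct rows (sampled without replacement) are placed at farthest-point
    lattice positions; any remaining neurons start as the blend of their two
    nearest placed prototypes. Replicated data rows would otherwise seed
    several neurons with the same profile, which is a degenerate start: exact
    duplicates tie every best-match decision and the map cannot spread.
    """
    k = grid.n_neurons
    pos = grid.positions().astype(float)
    _, unique_idx = np.unique(X, axis=0, return_index=True)
    unique_idx = np.sort(unique_idx)
    take = min(k, unique_idx.shape[0])
    idx = rng.choice(unique_idx, size=take, replace=False)
    order = _farthest_point_order(grid)
    codebook = np.empty((k, X.shape[1]))
    placed = order[:take]
    codebook[placed] = X[idx]
    for p in order[take:]:
        nearest = sorted(
            placed, key=lambda c: (float(np.sum((pos[p] - pos[c]) ** 2)), c)
        )[:2]
        codebook[p] = codebook[nearest].mean(axis=0)
    return codebook


def train_som(
    data: ConditionTable,
    grid: GridSize,
    n_epochs: int = 100,
    seed: int = 0,
    final_radius: float = 0.3,
) -> SOMModel:
    """Train a batch SOM on a (scaled) condition table.

    The codebook is initialized from rows sampled without replacement (with
    replacement, plus a warning, if there are fewer rows than neurons — empty
    neurons are legal and simply attract no variables downstream).
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    X = np.asarray(data.values, dtype=float)
    n, m = X.shape
    k = grid.n_neurons
    rng = np.random.default_rng(seed)

    if n < k:
        warnings.warn(
            f"fewer variables ({n}) than neurons ({k}); some neurons will be empty"
        )
    codebook = _initial_codebook(X, grid, rng)

    pos = grid.positions().astype(float)
    # squared grid distances between neurons
    gd2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=2)

    sigma0 = max(grid.d1, grid.d2) / 2.0
    sigma_end = min(final_radius, sigma0)
    for epoch in range(n_epochs):
        frac = epoch / (n_epochs - 1) if n_epochs > 1 else 1.0
        sigma = sigma0 + (sigma_end - sigma0) * frac
        bmus = bmu_indices(codebook, X)
        H = np.exp(-gd2 / (2.0 * sigma * sigma))  # (k, k)
        W = H[:, bmus]  # (k, n) weight of row i on neuron j
        den = W.sum(axis=1)
        num = W @ X
        nonzero = den > 1e-300
        codebook[nonzero] = num[nonzero] / den[nonzero, None]

    final_bmus = bmu_indices(codebook, X)
    assignments = {vid: int(b) + 1 for vid, b in zip(data.variable_ids, final_bmus)}
    return SOMModel(
        grid=grid,
        codebook=codebook,
        measurement_labels=list(data.measurement_labels),
        initial_radius=sigma0,
        final_radius=sigma_end,
        n_epochs=n_epochs,
        seed=seed,
        training_assignments=assignments,
    )


def neuron_correlations(model: SOMModel, tol: float = 1e-12) -> CorrelationMatrix:
    """Pearson correlation between every pair of codebook rows."""
    C = model.codebook
    centered = C - C.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.sum(centered**2, axis=1))
    zero_var = norms <= tol
    safe = np.where(zero_var, 1.0, norms)
    unit = centered / safe[:, None]
    R = unit @ unit.T
    R = np.clip(R, -1.0, 1.0)
    R = (R + R.T) / 2.0
    R[zero_var, :] = 0.0
    R[:, zero_var] = 0.0
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(values=R, zero_variance=zero_var)


def quantization_error(model: SOMModel, data: ConditionTable) -> float:
    """Mean Euclidean distance from each row to its BMU prototype."""
    X = np.asarray(data.values, dtype=float)
    bmus = bmu_indices(model.codebook, X)
    return float(np.mean(np.linalg.norm(X - model.codebook[bmus], axis=1)))
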