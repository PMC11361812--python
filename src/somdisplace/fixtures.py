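"""Synthetic control/test condition pairs with planted ground truth.

The generator emulates the data geometry the pipeline assumes: a small set
of distinct base profiles over M ordered measurements, many noisy variable
copies per profile (the control condition), and a test condition in which
selected variables undergo a planted operation — identity, a shift of k
positions toward later/earlier measurements, a sign flip, or replacement by
an unrelated decoy pattern.

Because the reference map is trained on the control only, a displaced test
profile can only land on a neuron whose prototype *is* that displaced
pattern. The default profile set is therefore closed under the planted
operations: ``{g, shift(g, +1), -g, decoy}`` where ``g`` is a narrow
Gaussian bump (narrow so that the shifted sibling is a genuinely distinct
cluster, not a redundant one) and the decoy is a smooth curve orthogonalized
against the rest. Shift operations are planted only on families whose
shifted profile exists in the set, flips only where the negated profile
does, and replacements send the variable to the decoy family — which makes
every expected label exact at zero noise.

Base profiles are non-periodic by construction so a k-shift has a unique
cross-correlation peak; shifting extends the edges by linear extrapolation
(an "earlier/later activation" along a staged axis, not a wrap-around).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_scale import ConditionTable, VariableMetadata

__all__ = [
    "PlantedOp",
    "FixtureSpec",
    "FixtureTruth",
    "shift_profile",
    "gaussian_bump",
    "displacement_closure_profiles",
    "orthogonal_profiles",
    "standard_fixture_spec",
    "generate_fixture",
]

OPS = ("identity", "shift", "flip", "replace")


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return (x - x.mean()) / x.std(ddof=1)


def gaussian_bump(m: int, center: float | None = None, width: float | None = None) -> np.ndarray:
    """A smooth unimodal curve over ``m`` points (not z-scored)."""
    t = np.arange(m, dtype=float)
    c = (m - 1) / 2.0 if center is None else center
    w = m / 7.0 if width is None else width
    return np.exp(-((t - c) ** 2) / (2.0 * w * w))


def shift_profile(x: np.ndarray, k: int) -> np.ndarray:
    """Shift a profile ``k`` positions toward later measurements (k may be < 0).

    Vacated edge positions are filled by linear extrapolation of the
    profile's own end slope, keeping the output length M.
    """
    x = np.asarray(x, dtype=float)
    m = x.shape[0]
    if abs(k) > m - 3:
        raise ValueError(f"shift magnitude {abs(k)} exceeds M-3 = {m - 3}")
    if k == 0:
        return x.copy()
    out = np.empty_like(x)
    if k > 0:
        out[k:] = x[: m - k]
        slope = x[1] - x[0]
        out[:k] = x[0] - slope * np.arange(k, 0, -1)
    else:
        j = -k
        out[: m - j] = x[j:]
        slope = x[-1] - x[-2]
        out[m - j:] = x[-1] + slope * np.arange(1, j + 1)
    return out


def displacement_closure_profiles(m: int = 7) -> np.ndarray:
    """The default 4-family base set: ``[g, shift(g,+1), -g, decoy]``.

    The decoy is a W-shaped (alternating-slope) curve orthogonalized, after
    centering, against the span of the other families: its lag-0 correlation
    with each of them is exactly 0, and — because its short windows are far
    from collinear with the bump's tails — its lagged window correlations
    stay well below any displacement call.
    """
    if m < 5:
        raise ValueError("closure profile set needs at least 5 measurements")
    g = gaussian_bump(m)
    g1 = shift_profile(g, +1)
    base = [g, g1]
    template = np.array([0.0, -1.0, 0.3, -0.2, 0.5, -1.0, 0.2])
    seed_curve = np.interp(
        np.linspace(0.0, 1.0, m), np.linspace(0.0, 1.0, len(template)), template
    )
    decoy = _orthogonalize(seed_curve, base)
    return np.vstack([_zscore(g), _zscore(g1), _zscore(-g), _zscore(decoy)])


def _orthogonalize(curve: np.ndarray, against: list[np.ndarray]) -> np.ndarray:
    # build an orthonormal basis of the centered span first, then project out
    basis: list[np.ndarray] = []
    for b in against:
        bc = b - b.mean()
        for e in basis:
            bc = bc - np.dot(bc, e) * e
        norm = np.linalg.norm(bc)
        if norm > 1e-12:
            basis.append(bc / norm)
    v = curve - curve.mean()
    for e in basis:
        v = v - np.dot(v, e) * e
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("decoy curve lies in the span of the base profiles")
    return v / n


def orthogonal_profiles(m: int, k: int, seed: int = 0) -> np.ndarray:
    """K smooth base profiles with pairwise Pearson correlation exactly 0.

    Built by centered Gram-Schmidt over a bank of smooth seed curves
    (polynomials, sigmoids, bumps). Requires ``k <= m - 1`` (centered
    vectors live in an (m-1)-dimensional space).
    """
    if k > m - 1:
        raise ValueError(f"cannot build {k} orthogonal centered profiles with M={m}")
    rng = np.random.default_rng(seed)
    t = np.linspace(-1.0, 1.0, m)
    bank = [
        t,
        t**2,
        np.tanh(3.0 * t),
        gaussian_bump(m, center=(m - 1) * 0.3),
        t**3,
        gaussian_bump(m, center=(m - 1) * 0.7),
        np.abs(t),
        np.tanh(3.0 * (t - 0.3)),
    ]
    out: list[np.ndarray] = []
    i = 0
    while len(out) < k:
        if i < len(bank):
            curve = bank[i]
        else:  # fall back to smooth random curves if the bank runs dry
            curve = np.cumsum(rng.normal(size=m))
        i += 1
        try:
            v = _orthogonalize(curve, out)
        except ValueError:
            continue
        out.append(v)
    return np.vstack([_zscore(v) for v in out])


@dataclass(frozen=True)
class PlantedOp:
    """One planted operation applied to an explicit set of variables."""

    op: str
    variables: tuple[str, ...]
    k: int = 0

    def __post_init__(self) -> None:
        if self.op not in OPS:
            raise ValueError(f"unknown op {self.op!r}; must be one of {OPS}")
        if self.op == "shift" and self.k == 0:
            raise ValueError("shift op requires k != 0")
        if self.op != "shift" and self.k != 0:
            raise ValueError(f"op {self.op!r} takes no k")


@dataclass
class FixtureSpec:
    """Recipe for one control/test fixture pair.

    ``profiles`` is the (K, M) base-profile matrix (rows are families, in
    z-scored units); the LAST family is the decoy target of ``replace`` ops.
    ``noise_sd`` is in units of the scaled profile's standard deviation.
    Variables not named by any planted op stay identical (up to noise).
    """

    n_measurements: int
    profiles: np.ndarray
    variables_per_profile: int
    noise_sd: float = 0.0
    planted_ops: list[PlantedOp] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.n_measurements < 4:
            raise ValueError("need at least 4 measurements")
        if self.profiles.ndim != 2 or self.profiles.shape[1] != self.n_measurements:
            raise ValueError("profiles must be a (K, M) matrix")
        if self.variables_per_profile < 1:
            raise ValueError("variables_per_profile must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        seen: set[str] = set()
        for op in self.planted_ops:
            if op.op == "shift" and abs(op.k) > self.n_measurements - 3:
                raise ValueError(
                    f"shift magnitude {abs(op.k)} exceeds M-3 = {self.n_measurements - 3}"
                )
            overlap = seen.intersection(op.variables)
            if overlap:
                raise ValueError(f"planted ops overlap on variables {sorted(overlap)}")
            seen.update(op.variables)

    @property
    def n_families(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_variables(self) -> int:
        return self.n_families * self.variables_per_profile

    def variable_ids(self) -> list[str]:
        return [
            f"fam{f + 1}_v{j:03d}"
            for f in range(self.n_families)
            for j in range(self.variables_per_profile)
        ]


@dataclass
class FixtureTruth:
    """Planted per-variable ground truth.

    ``expected_label`` is the displacement label the pipeline should recover
    at zero noise (``conserved``, ``early``, ``delay``, ``flip``, ``other``).
    """

    frame: pd.DataFrame  # variable_id, family, op, k, expected_label

    def label_of(self, variable_id: str) -> str:
        return self.frame.set_index("variable_id").loc[variable_id, "expected_label"]

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _expected_label(op: str, k: int, family: int, n_families: int) -> str:
    if op == "identity":
        return "conserved"
    if op == "shift":
        return "delay" if k > 0 else "early"
    if op == "flip":
        return "flip"
    if op == "replace":
        # replacing a decoy-family variable with the decoy profile is a no-op
        return "conserved" if family == n_families - 1 else "other"
    raise ValueError(op)


def generate_fixture(
    spec: FixtureSpec,
) -> tuple[ConditionTable, ConditionTable, VariableMetadata, FixtureTruth]:
    """Build (control, test, metadata, truth) for a fixture spec.

    Control rows are the family profile plus independent Gaussian noise;
    test rows apply the planted op to the family profile before adding an
    independent noise draw. Deterministic per ``spec.seed``. Metadata assigns
    each variable a ``kind`` (gene/phenotype, round-robin) and its family.
    """
    rng = np.random.default_rng(spec.seed)
    ids = spec.variable_ids()
    op_of: dict[str, tuple[str, int]] = {v: ("identity", 0) for v in ids}
    for op in spec.planted_ops:
        for v in op.variables:
            if v not in op_of:
                raise ValueError(f"planted op names unknown variable {v!r}")
            op_of[v] = (op.op, op.k)

    m = spec.n_measurements
    control = np.empty((spec.n_variables, m))
    test = np.empty((spec.n_variables, m))
    truth_rows = []
    i = 0
    for f in range(spec.n_families):
        base = spec.profiles[f]
        for _ in range(spec.variables_per_profile):
            vid = ids[i]
            opname, k = op_of[vid]
            if opname == "identity":
                target = base
            elif opname == "shift":
                target = shift_profile(base, k)
            elif opname == "flip":
                target = -base
            else:  # replace → the designated decoy family profile
                target = spec.profiles[-1]
            control[i] = base + rng.normal(0.0, spec.noise_sd, m)
            test[i] = target + rng.normal(0.0, spec.noise_sd, m)
            truth_rows.append(
                {"variable_id": vid, "family": f"fam{f + 1}", "op": opname, "k": k,
                 "expected_label": _expected_label(opname, k, f, spec.n_families)}
            )
            i += 1

    labels = [f"m{j + 1}" for j in range(m)]
    control_table = ConditionTable("control", ids, labels, control)
    test_table = ConditionTable("test", ids, labels, test)
    meta = VariableMetadata(
        pd.DataFrame(
            {
                "kind": ["gene" if j % 2 == 0 else "phenotype" for j in range(len(ids))],
                "family": [r["family"] for r in truth_rows],
            },
            index=pd.Index(ids, name="variable_id"),
        )
    )
    truth = FixtureTruth(
        pd.DataFrame(truth_rows,
                     columns=["variable_id", "family", "op", "k", "expected_label"])
    )
    return control_table, test_table, meta, truth


def standard_fixture_spec(
    seed: int = 0,
    n_measurements: int = 7,
    variables_per_profile: int = 25,
    noise_sd: float = 0.0,
) -> FixtureSpec:
    """The canonical 4-family / 100-variable fixture.

    Planted operations (with 25 variables per family):
    60 identity, 15 shifts of one position (5 later on family 1, 10 earlier
    on family 2), 15 flips (5 on family 1, 10 on family 3) and 10
    replacements by the decoy pattern (4/3/3 on families 1-3).
    Smaller ``variables_per_profile`` scales the op counts proportionally.
    """
    profiles = displacement_closure_profiles(n_measurements)
    v = variables_per_profile

    def fam(f: int, lo: int, hi: int) -> tuple[str, ...]:
        return tuple(f"fam{f}_v{j:03d}" for j in range(lo, min(hi, v)))

    def frac(x: int) -> int:  # scale the canonical counts for small fixtures
        return max(1, round(x * v / 25))

    a, b, c = frac(5), frac(10), frac(4)
    ops = [
        PlantedOp("shift", fam(1, 0, a), k=+1),
        PlantedOp("flip", fam(1, a, 2 * a)),
        PlantedOp("replace", fam(1, 2 * a, 2 * a + c)),
        PlantedOp("shift", fam(2, 0, b), k=-1),
        PlantedOp("replace", fam(2, b, b + frac(3))),
        PlantedOp("flip", fam(3, 0, b)),
        PlantedOp("replace", fam(3, b, b + frac(3))),
    ]
    return FixtureSpec(
        n_measurements=n_measurements,
        profiles=profiles,
        variables_per_profile=v,
        noise_sd=noise_sd,
        planted_ops=ops,
        seed=seed,
    )
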