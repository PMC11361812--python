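"""Classification of neuron-pair relationships by lagged cross-correlation.

A variable is *conserved* when it occupies the same neuron in the test
condition as in the reference. When it moves, the nature of the move is read
off the relationship between the two neurons' prototype profiles:

* **delay** — the destination prototype is the source pattern shifted toward
  later measurements: the cross-correlation peaks at a positive lag above
  ``delay_threshold``;
* **early** — the mirror image, peak at a negative lag;
* **flip**  — opposite behavior: the lag-0 correlation is at or below
  ``flip_threshold`` (a strong anti-correlation);
* **other** — none of the above (an unrelated pattern).

The lag convention: at lag ``k > 0`` the first ``M-k`` points of the source
are correlated with the last ``M-k`` points of the destination, so a positive
peak lag means the destination's pattern happens *later* along the
measurement axis. Each lag's correlation is a plain Pearson correlation on
the overlapping sub-series (re-centered per window). Lags are bounded so at
least ``min_overlap`` points overlap (Pearson is not meaningful below 3).

Precedence of the rules is flip > delay/early > conserved-like > other: a
strongly anti-correlated pair can also show an off-center positive peak, and
flip — "completely opposite behavior" — is the most specific call. Peak-lag
ties are broken toward lag 0 (prefer the conservative call) and then toward
the negative lag.

Because a large-lag window holds very few points, two unrelated smooth
profiles routinely produce near-perfect correlations there (three points are
almost always close to collinear). The classifier therefore only lets a lag
compete for the peak if its correlation is significant given the window
length (one-sided t-test at ``peak_alpha``): an exact shift still scores
r = 1 (always significant) at its true lag, while chance 3-point alignments
are ignored. Set ``peak_alpha=None`` to disable the gate and rank raw peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .som_engine import SOMModel

__all__ = [
    "DisplacementConfig",
    "CrossCorrelationProfile",
    "PairRelation",
    "RelationshipMatrix",
    "EdgeTable",
    "cross_correlation_profile",
    "classify_pair",
    "detect_displacements",
    "label_variables",
    "net_edges",
]

RELATIONS = ("conserved", "early", "delay", "flip", "other")


@dataclass(frozen=True)
class DisplacementConfig:
    """Thresholds for the relationship classifier.

    delay_threshold
        Minimum (strict) peak correlation for an off-center peak to count as
        an early/delay displacement; also the bar for the conserved-like
        pair relation at lag 0. In (0, 1].
    flip_threshold
        Lag-0 correlation at or below this (strict "lower than") is a flip.
        In [-1, 0).
    min_overlap
        Minimum overlapping points per lag window (>= 3).
    peak_alpha
        Significance level of the per-window t-test gating peak selection
        (None disables the gate).
    """

    delay_threshold: float = 0.8
    flip_threshold: float = -0.8
    min_overlap: int = 3
    peak_alpha: float | None = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.delay_threshold <= 1.0:
            raise ValueError("delay_threshold must be in (0, 1]")
        if not -1.0 <= self.flip_threshold < 0.0:
            raise ValueError("flip_threshold must be in [-1, 0)")
        if self.min_overlap < 3:
            raise ValueError("min_overlap must be >= 3")
        if self.peak_alpha is not None and not 0.0 < self.peak_alpha < 1.0:
            raise ValueError("peak_alpha must be in (0, 1) or None")


@dataclass
class CrossCorrelationProfile:
    """Per-lag Pearson correlations between two equal-length series."""

    lags: np.ndarray
    correlations: np.ndarray
    peak_lag: int
    peak_value: float

    @property
    def lag0_value(self) -> float:
        return float(self.correlations[list(self.lags).index(0)])


@dataclass(frozen=True)
class PairRelation:
    relation: str
    peak_lag: int
    peak_value: float
    lag0_value: float


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; 0 when either side has zero variance on the window."""
    xc = x - x.mean()
    yc = y - y.mean()
    nx = float(np.sqrt(np.sum(xc**2)))
    ny = float(np.sqrt(np.sum(yc**2)))
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.clip(np.dot(xc, yc) / (nx * ny), -1.0, 1.0))


def cross_correlation_profile(
    a: np.ndarray,
    b: np.ndarray,
    min_overlap: int = 3,
) -> CrossCorrelationProfile:
    """Lagged Pearson correlations between series ``a`` (source) and ``b``.

    At lag ``k > 0``: ``corr(a[:M-k], b[k:])`` — positive lag means ``b``'s
    pattern occurs later. Lags run from ``-(M - min_overlap)`` to
    ``+(M - min_overlap)``. The peak is the maximum correlation; ties are
    broken toward lag 0, then toward the negative lag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("series contain non-finite values")
    m = a.shape[0]
    if min_overlap < 3:
        raise ValueError("min_overlap must be >= 3")
    if m < min_overlap:
        raise ValueError(f"series length {m} below min_overlap {min_overlap}")
    kmax = m - min_overlap
    lags = np.arange(-kmax, kmax + 1)
    corrs = np.empty(lags.shape[0])
    for i, k in enumerate(lags):
        if k >= 0:
            corrs[i] = _pearson(a[: m - k], b[k:])
        else:
            corrs[i] = _pearson(a[-k:], b[: m + k])
    # peak with ties toward 0 then toward negative lag
    order = sorted(range(len(lags)), key=lambda i: (abs(int(lags[i])), int(lags[i])))
    best = order[0]
    for i in order[1:]:
        if corrs[i] > corrs[best]:
            best = i
    return CrossCorrelationProfile(
        lags=lags,
        correlations=corrs,
        peak_lag=int(lags[best]),
        peak_value=float(corrs[best]),
    )


def critical_correlation(n_points: int, alpha: float) -> float:
    """Smallest r significant at one-sided level ``alpha`` with ``n_points``."""
    df = n_points - 2
    if df < 1:
        return 1.0
    t_c = float(stats.t.ppf(1.0 - alpha, df))
    return t_c / np.sqrt(t_c * t_c + df)


def _classification_peak(
    prof: CrossCorrelationProfile,
    m: int,
    alpha: float | None,
) -> tuple[int, float, bool]:
    """Peak (lag, value, qualifies) over lags clearing the per-window t-test.

    When no lag is significant the raw peak is reported for transparency but
    flagged as not qualifying — a correlation that a window of that length
    produces by chance cannot support a displacement call. ``alpha`` is
    Bonferroni-split across the lags so the gate controls the family-wise
    chance of any window qualifying. Ties break toward lag 0, then toward
    the negative lag.
    """
    if alpha is None:
        return prof.peak_lag, prof.peak_value, True
    alpha_eff = alpha / len(prof.lags)
    order = sorted(
        range(len(prof.lags)),
        key=lambda i: (abs(int(prof.lags[i])), int(prof.lags[i])),
    )
    best = None
    for i in order:
        n_k = m - abs(int(prof.lags[i]))
        if prof.correlations[i] >= critical_correlation(n_k, alpha_eff) - 1e-12:
            if best is None or prof.correlations[i] > prof.correlations[best]:
                best = i
    if best is None:
        return prof.peak_lag, prof.peak_value, False
    return int(prof.lags[best]), float(prof.correlations[best]), True


def classify_pair(
    a: np.ndarray,
    b: np.ndarray,
    config: DisplacementConfig | None = None,
) -> PairRelation:
    """Classify the relationship of destination profile ``b`` to source ``a``."""
    config = config or DisplacementConfig()
    prof = cross_correlation_profile(a, b, config.min_overlap)
    lag0 = prof.lag0_value
    peak_lag, peak_value, qualifies = _classification_peak(
        prof, np.asarray(a).shape[0], config.peak_alpha
    )
    if lag0 <= config.flip_threshold:
        relation = "flip"
    elif qualifies and peak_lag > 0 and peak_value > config.delay_threshold:
        relation = "delay"
    elif qualifies and peak_lag < 0 and peak_value > config.delay_threshold:
        relation = "early"
    elif qualifies and peak_lag == 0 and peak_value > config.delay_threshold:
        relation = "conserved"
    else:
        relation = "other"
    return PairRelation(relation, peak_lag, peak_value, lag0)


@dataclass
class RelationshipMatrix:
    """Relation of every ordered neuron pair of a trained map."""

    n_neurons: int
    pairs: dict[tuple[int, int], PairRelation] = field(default_factory=dict)
    config: DisplacementConfig = field(default_factory=DisplacementConfig)

    def relation(self, from_neuron: int, to_neuron: int) -> PairRelation:
        try:
            return self.pairs[(from_neuron, to_neuron)]
        except KeyError:
            raise KeyError(
                f"neuron pair ({from_neuron}, {to_neuron}) outside 1..{self.n_neurons}"
            ) from None

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"from_neuron": f, "to_neuron": t, "relation": r.relation,
             "peak_lag": r.peak_lag, "peak_value": r.peak_value,
             "lag0_value": r.lag0_value}
            for (f, t), r in sorted(self.pairs.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["from_neuron", "to_neuron", "relation",
                     "peak_lag", "peak_value", "lag0_value"],
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def detect_displacements(
    model: SOMModel,
    config: DisplacementConfig | None = None,
) -> RelationshipMatrix:
    """Classify every ordered pair of the model's neuron prototypes.

    The diagonal is conserved by definition (a variable that stayed put).
    """
    config = config or DisplacementConfig()
    if config.min_overlap > model.n_measurements:
        raise ValueError("min_overlap exceeds the number of measurements")
    out = RelationshipMatrix(n_neurons=model.n_neurons, config=config)
    k = model.n_neurons
    for f in range(1, k + 1):
        for t in range(1, k + 1):
            if f == t:
                prof = cross_correlation_profile(
                    model.codebook[f - 1], model.codebook[f - 1], config.min_overlap
                )
                out.pairs[(f, t)] = PairRelation(
                    "conserved", 0, prof.lag0_value, prof.lag0_value
                )
            else:
                out.pairs[(f, t)] = classify_pair(
                    model.codebook[f - 1], model.codebook[t - 1], config
                )
    return out


def label_variables(mapping, relations: RelationshipMatrix) -> pd.DataFrame:
    """Per-variable displacement label for each test condition.

    A variable keeping its neuron is ``conserved``; otherwise it takes the
    relation of (reference neuron -> test neuron). Returns a long-format
    frame: variable_id, condition, from_neuron, to_neuron, label.
    """
    rows = []
    frame = mapping.frame
    for cond in mapping.test_condition_names:
        for vid, ref, test in zip(
            frame["variable_id"], frame["ref_neuron"], frame[f"{cond}_neuron"]
        ):
            ref, test = int(ref), int(test)
            if not (1 <= test <= relations.n_neurons and 1 <= ref <= relations.n_neurons):
                raise KeyError(
                    f"neuron id outside relationship matrix for variable {vid!r}"
                )
            label = "conserved" if ref == test else relations.relation(ref, test).relation
            rows.append(
                {"variable_id": vid, "condition": cond,
                 "from_neuron": ref, "to_neuron": test, "label": label}
            )
    return pd.DataFrame(
        rows, columns=["variable_id", "condition", "from_neuron", "to_neuron", "label"]
    )


@dataclass
class EdgeTable:
    """Aggregated displacement flows between neuron pairs.

    ``edges`` has one row per (condition, from, to, relation[, group]) with
    the number of variables taking that move; conserved variables are not
    edges but are tallied in ``conserved_summary`` so that per condition
    edge counts + conserved = N.
    """

    edges: pd.DataFrame
    conserved_summary: pd.DataFrame
    group_by: str | None = None

    def write_csv(self, path) -> None:
        self.edges.to_csv(path, index=False)


def net_edges(
    labels: pd.DataFrame,
    mapping,
    group_by: str | None = None,
) -> EdgeTable:
    """Aggregate per-variable labels into displacement flow counts."""
    frame = labels.copy()
    if group_by is not None:
        meta_cols = mapping.metadata_columns
        if group_by not in meta_cols:
            raise KeyError(
                f"unknown group attribute {group_by!r}; available: {meta_cols}"
            )
        attr = mapping.frame.set_index("variable_id")[group_by]
        frame[group_by] = frame["variable_id"].map(attr)

    moved = frame[frame["label"] != "conserved"]
    keys = ["condition", "from_neuron", "to_neuron", "relation"]
    moved = moved.rename(columns={"label": "relation"})
    if group_by is not None:
        keys.append(group_by)
    if len(moved):
        edges = (
            moved.groupby(keys, dropna=False, observed=True)
            .size()
            .reset_index(name="count")
            .sort_values(keys, kind="stable")
            .reset_index(drop=True)
        )
    else:
        edges = pd.DataFrame(columns=keys + ["count"])

    conserved = (
        frame[frame["label"] == "conserved"]
        .groupby("condition")
        .size()
        .reindex(frame["condition"].unique(), fill_value=0)
        .rename("conserved")
        .reset_index()
        .rename(columns={"index": "condition"})
    )
    return EdgeTable(edges=edges, conserved_summary=conserved, group_by=group_by)
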