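"""Allocation bar charts and the displacement flow graph.

Neurons are drawn as circles on their grid positions with area proportional
to the number of variables allocated to them; displacement flows are arrows
between neurons, colored by relation and weighted by the variable count.
Arrow endpoints are fixed grid positions, so the count is encoded as line
width plus a printed label rather than arrow length. Alongside every figure
a machine-readable *sidecar* CSV of the drawn elements is written (columns:
element_type, from, to, relation, weight, x, y) — plots are verified through
their sidecars, never pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .condition_mapper import MappingResult, allocation_counts  # noqa: E402
from .displacement import EdgeTable  # noqa: E402

__all__ = ["PlotSpec", "plot_allocations", "plot_displacements", "sidecar_path"]

DEFAULT_COLORS = {
    "early": "#1f77b4",
    "delay": "#d62728",
    "flip": "#9467bd",
    "other": "#7f7f7f",
    "conserved": "#2ca02c",
}


@dataclass
class PlotSpec:
    """Visual parameters; scales are per-variable-count factors."""

    circle_scale: float = 60.0   # marker area (pt^2) per variable
    arrow_scale: float = 0.5     # line width (pt) per variable
    color_map: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))
    group_filter: tuple[str, str] | None = None  # (attribute, value)
    output_format: str = "png"

    def __post_init__(self) -> None:
        if self.circle_scale <= 0 or self.arrow_scale <= 0:
            raise ValueError("scales must be positive")
        if self.output_format not in ("png", "svg"):
            raise ValueError("output_format must be 'png' or 'svg'")

    def color(self, relation: str) -> str:
        try:
            return self.color_map[relation]
        except KeyError:
            raise KeyError(f"no color assigned to relation {relation!r}") from None


def sidecar_path(out) -> str:
    return f"{out}.elements.csv"


def _grid_xy(neuron_id: int, d2: int) -> tuple[float, float]:
    row, col = divmod(neuron_id - 1, d2)
    return float(col), float(-row)  # top-left neuron 1 at the top


def plot_allocations(mapping: MappingResult, spec: PlotSpec, out) -> str:
    """Grouped bar chart of variables per neuron, one bar set per condition."""
    if mapping.n_variables == 0:
        raise ValueError("empty mapping: nothing to plot")
    conditions = mapping.condition_names
    counts = {c: allocation_counts(mapping, c) for c in conditions}
    neurons = np.arange(1, mapping.n_neurons + 1)
    width = 0.8 / len(conditions)

    fig, ax = plt.subplots(figsize=(max(6, mapping.n_neurons * 0.9), 4))
    rows = []
    for i, cond in enumerate(conditions):
        offset = (i - (len(conditions) - 1) / 2) * width
        ax.bar(neurons + offset, counts[cond].to_numpy(), width=width, label=cond)
        for n in neurons:
            rows.append(
                {"element_type": "bar", "from": int(n), "to": "", "relation": cond,
                 "weight": int(counts[cond].loc[n]), "x": float(n + offset), "y": 0.0}
            )
    ax.set_xlabel("neuron")
    ax.set_ylabel("variables allocated")
    ax.set_xticks(neurons)
    ax.legend(title="condition")
    fig.tight_layout()
    fig.savefig(out, format=spec.output_format)
    plt.close(fig)
    _write_sidecar(rows, out)
    return str(out)


def plot_displacements(
    mapping: MappingResult,
    edges: EdgeTable,
    spec: PlotSpec,
    out,
    grid_d2: int | None = None,
    reference_condition: str | None = None,
) -> str:
    """Displacement graph: circles sized by allocation, arrows by flow count.

    ``spec.group_filter = (attribute, value)`` restricts the drawn flows to
    an edge-table group column produced by ``net_edges(..., group_by=attr)``.
    Bidirectional flows become two slightly offset arrows.
    """
    if mapping.n_variables == 0:
        raise ValueError("empty mapping: nothing to plot")
    d2 = grid_d2 if grid_d2 is not None else _infer_d2(mapping.n_neurons)
    ref = reference_condition or mapping.control_name
    alloc = allocation_counts(mapping, ref)

    flows = edges.edges.copy()
    if spec.group_filter is not None:
        attr, value = spec.group_filter
        if attr not in flows.columns:
            raise KeyError(
                f"edge table has no group column {attr!r}; "
                "rebuild it with net_edges(..., group_by=...)"
            )
        flows = flows[flows[attr] == value]
    if len(flows):
        bad = set(flows["from_neuron"]).union(flows["to_neuron"]) - set(
            range(1, mapping.n_neurons + 1)
        )
        if bad:
            raise ValueError(f"edge table references unknown neurons: {sorted(bad)}")

    fig, ax = plt.subplots(figsize=(6, 6))
    rows = []
    for n in range(1, mapping.n_neurons + 1):
        x, y = _grid_xy(n, d2)
        c = int(alloc.loc[n])
        ax.scatter([x], [y], s=max(spec.circle_scale * c, 1.0), zorder=2,
                   color="#c6dbef", edgecolor="#333333")
        ax.annotate(str(n), (x, y), ha="center", va="center", zorder=3)
        rows.append(
            {"element_type": "circle", "from": n, "to": "", "relation": "",
             "weight": c, "x": x, "y": y}
        )
    pair_seen: dict[tuple[int, int], int] = {}
    for _, e in flows.sort_values(list(flows.columns), kind="stable").iterrows():
        f, t = int(e["from_neuron"]), int(e["to_neuron"])
        x1, y1 = _grid_xy(f, d2)
        x2, y2 = _grid_xy(t, d2)
        key = (min(f, t), max(f, t))
        # offset repeated/bidirectional arrows sideways so both stay visible
        k = pair_seen.get(key, 0)
        pair_seen[key] = k + 1
        dx, dy = x2 - x1, y2 - y1
        norm = float(np.hypot(dx, dy)) or 1.0
        ox, oy = -dy / norm * 0.07 * k, dx / norm * 0.07 * k
        count = int(e["count"])
        ax.annotate(
            "",
            xy=(x2 + ox, y2 + oy), xytext=(x1 + ox, y1 + oy),
            arrowprops=dict(
                arrowstyle="-|>", lw=spec.arrow_scale * count,
                color=spec.color(str(e["relation"])), shrinkA=16, shrinkB=16,
            ),
            zorder=1,
        )
        ax.annotate(
            str(count),
            ((x1 + x2) / 2 + ox, (y1 + y2) / 2 + oy),
            fontsize=8, ha="center",
            color=spec.color(str(e["relation"])),
        )
        rows.append(
            {"element_type": "arrow", "from": f, "to": t,
             "relation": str(e["relation"]), "weight": count,
             "x": (x1 + x2) / 2, "y": (y1 + y2) / 2}
        )
    ax.set_xlim(-0.8, d2 - 0.2)
    d1 = int(np.ceil(mapping.n_neurons / d2))
    ax.set_ylim(-(d1 - 1) - 0.8, 0.8)
    ax.set_aspect("equal")
    ax.axis("off")
    handles = [
        plt.Line2D([0], [0], color=spec.color(r), lw=2, label=r)
        for r in sorted(set(flows["relation"].astype(str))) if len(flows)
    ]
    if handles:
        ax.legend(handles=handles, loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(out, format=spec.output_format)
    plt.close(fig)
    _write_sidecar(rows, out)
    return str(out)


def _infer_d2(n_neurons: int) -> int:
    # fall back to a near-square layout when the true grid is unknown
    return int(np.ceil(np.sqrt(n_neurons)))


def _write_sidecar(rows: list[dict], out) -> None:
    pd.DataFrame(
        rows, columns=["element_type", "from", "to", "relation", "weight", "x", "y"]
    ).to_csv(sidecar_path(out), index=False)
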