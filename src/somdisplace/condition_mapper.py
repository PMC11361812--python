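"""Projection of test conditions onto the reference map.

Every variable's reference location comes from the trained model's own
assignments; its test location is the best-matching unit of its scaled
test-condition profile. The joined table — variable id, metadata attributes,
reference neuron, one (neuron, conserved) column pair per test condition —
is the *class dataframe* users export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_scale import ScaledConditionSet, VariableMetadata
from .som_engine import SOMModel, bmu_indices

__all__ = ["MappingResult", "create_mappings", "allocation_counts"]


@dataclass
class MappingResult:
    """The class dataframe plus per-condition neuron allocation counts.

    ``frame`` columns: variable_id, <metadata...>, ref_neuron, then per test
    condition ``<name>_neuron`` and ``<name>_conserved``.
    """

    frame: pd.DataFrame
    control_name: str
    test_condition_names: list[str]
    n_neurons: int
    metadata_columns: list[str] = field(default_factory=list)

    @property
    def n_variables(self) -> int:
        return len(self.frame)

    @property
    def condition_names(self) -> list[str]:
        return [self.control_name] + self.test_condition_names

    def neuron_column(self, condition: str) -> str:
        if condition == self.control_name:
            return "ref_neuron"
        if condition in self.test_condition_names:
            return f"{condition}_neuron"
        raise KeyError(
            f"unknown condition {condition!r}; have {self.condition_names}"
        )

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def create_mappings(
    model: SOMModel,
    scaled: ScaledConditionSet,
    metadata: VariableMetadata | None = None,
) -> MappingResult:
    """Assemble the class dataframe for all test conditions.

    Reference neurons are the model's training assignments (the map was
    trained on the control; under the deterministic batch trainer these are
    the control BMUs). Test neurons are computed by BMU lookup per condition.
    Metadata is left-joined; variables without metadata keep empty attributes.
    """
    control = scaled.control
    missing = [v for v in control.variable_ids if v not in model.training_assignments]
    if missing:
        raise ValueError(
            f"model has no training assignment for {len(missing)} variable(s) "
            f"(model/data mismatch), e.g. {missing[:5]}"
        )
    frame = pd.DataFrame({"variable_id": control.variable_ids})
    meta_cols: list[str] = []
    if metadata is not None and len(metadata.frame.columns):
        meta_cols = metadata.attribute_names
        known = frame["variable_id"].isin(metadata.frame.index)
        if (~known).any():
            warnings.warn(
                f"{int((~known).sum())} variable(s) missing from metadata; "
                "kept with empty attributes"
            )
        frame = frame.join(metadata.frame, on="variable_id")
    frame["ref_neuron"] = [
        model.training_assignments[v] for v in control.variable_ids
    ]
    for cond in scaled.test_conditions:
        # rows are aligned across conditions by construction of the scaled set
        sub = cond.subset(control.variable_ids)
        bmus = bmu_indices(model.codebook, np.asarray(sub.values, dtype=float)) + 1
        frame[f"{cond.condition_name}_neuron"] = bmus.astype(int)
        frame[f"{cond.condition_name}_conserved"] = (
            frame[f"{cond.condition_name}_neuron"] == frame["ref_neuron"]
        )
    return MappingResult(
        frame=frame,
        control_name=control.condition_name,
        test_condition_names=[c.condition_name for c in scaled.test_conditions],
        n_neurons=model.n_neurons,
        metadata_columns=meta_cols,
    )


def allocation_counts(mapping: MappingResult, condition: str) -> pd.Series:
    """Variables per neuron for one condition, zeros included; sums to N."""
    col = mapping.neuron_column(condition)
    counts = (
        mapping.frame[col]
        .value_counts()
        .reindex(range(1, mapping.n_neurons + 1), fill_value=0)
        .sort_index()
    )
    counts.index.name = "neuron"
    counts.name = condition
    return counts
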