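import numpy as np
import pytest

from somdisplace.fixtures import generate_fixture, standard_fixture_spec
from somdisplace.grid_optimizer import OptimizerConfig, build_reference_som
from somdisplace.io_scale import ConditionTable, scale_conditions
from somdisplace.som_engine import GridSize, SOMModel


def make_table(values, name="cond", ids=None, labels=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return ConditionTable(
        condition_name=name,
        variable_ids=ids or [f"g{i + 1}" for i in range(n)],
        measurement_labels=labels or [f"s{j + 1}" for j in range(m)],
        values=values,
    )


def make_model(codebook, d1, d2, **kw):
    codebook = np.asarray(codebook, dtype=float)
    return SOMModel(
        grid=GridSize(d1, d2),
        codebook=codebook,
        measurement_labels=[f"s{j + 1}" for j in range(codebook.shape[1])],
        initial_radius=1.0,
        final_radius=0.3,
        n_epochs=1,
        seed=0,
        **kw,
    )


@pytest.fixture(scope="session")
def pipeline_run():
    """One full pipeline run on the canonical noisy fixture (shared)."""
    from somdisplace.condition_mapper import create_mappings
    from somdisplace.displacement import (
        detect_displacements, label_variables, net_edges,
    )

    spec = standard_fixture_spec(seed=11, noise_sd=0.05)
    control, test, meta, truth = generate_fixture(spec)
    scaled = scale_conditions([control, test])
    model, diag = build_reference_som(scaled.control, OptimizerConfig(seed=11))
    mapping = create_mappings(model, scaled, meta)
    relations = detect_displacements(model)
    labels = label_variables(mapping, relations)
    edges = net_edges(labels, mapping)
    return {
        "spec": spec, "truth": truth, "scaled": scaled, "model": model,
        "diagnostics": diag, "mapping": mapping, "relations": relations,
        "labels": labels, "edges": edges, "metadata": meta,
    }
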