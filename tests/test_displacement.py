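import numpy as np
import pandas as pd
import pytest

from somdisplace.displacement import (
    DisplacementConfig,
    classify_pair,
    cross_correlation_profile,
    detect_displacements,
    label_variables,
    net_edges,
)
from somdisplace.fixtures import displacement_closure_profiles, shift_profile
from somdisplace.som_engine import GridSize, train_som

from conftest import make_model, make_table


class TestCrossCorrelationProfile:
    def test_identical_series_peak_at_zero(self):
        a = np.array([0.3, -1.2, 0.8, 2.0, -0.5])
        prof = cross_correlation_profile(a, a)
        assert prof.lag0_value == pytest.approx(1.0)
        assert prof.peak_lag == 0
        assert prof.peak_value == pytest.approx(1.0)

    def test_negated_series_lag0_minus_one(self):
        a = np.array([0.3, -1.2, 0.8, 2.0, -0.5])
        assert cross_correlation_profile(a, -a).lag0_value == pytest.approx(-1.0)

    def test_later_shifted_ramp_peaks_at_plus_one(self):
        # b is a delayed by one position; 5-point overlap is exactly linear
        a = np.array([0.0, 1, 2, 3, 4, 5])
        b = np.array([0.0, 0, 1, 2, 3, 4])
        prof = cross_correlation_profile(a, b)
        assert prof.peak_lag == 1
        assert prof.peak_value == pytest.approx(1.0)
        assert prof.lags.tolist() == [-3, -2, -1, 0, 1, 2, 3]

    def test_zero_variance_window_recorded_as_zero(self):
        a = np.array([1.0, 1, 1, 2, 3, 4])
        b = np.array([0.0, 1, 2, 3, 4, 5])
        prof = cross_correlation_profile(a, b)
        # at lag +3, a[:3] is constant -> correlation 0 by convention
        assert prof.correlations[list(prof.lags).index(3)] == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_correlation_profile(np.ones(5), np.ones(6))

    @pytest.mark.parametrize("k", [-4, -3, -2, -1, 1, 2, 3, 4])
    def test_exact_shift_peak_lag_equals_k(self, k):
        base = displacement_closure_profiles(7)[0]
        prof = cross_correlation_profile(base, shift_profile(base, k))
        assert prof.peak_lag == k
        assert prof.peak_value == pytest.approx(1.0, abs=1e-12)


class TestClassifyPair:
    def test_identical_profiles_are_conserved(self):
        a = displacement_closure_profiles(7)[0]
        assert classify_pair(a, a.copy()).relation == "conserved"

    @pytest.mark.parametrize("k", [-4, -3, -2, -1, 1, 2, 3, 4])
    def test_shift_recovery_direction_and_lag(self, k):
        base = displacement_closure_profiles(7)[0]
        rel = classify_pair(base, shift_profile(base, k))
        assert rel.relation == ("delay" if k > 0 else "early")
        assert rel.peak_lag == k

    def test_negated_profile_is_flip(self):
        a = displacement_closure_profiles(7)[0]
        rel = classify_pair(a, -a, DisplacementConfig(flip_threshold=-0.8))
        assert rel.relation == "flip"
        assert rel.lag0_value == pytest.approx(-1.0)

    def test_flip_takes_precedence_over_shifted_peak(self):
        # a vs -shift(a): anti-correlated at lag 0 AND a strong off-center peak
        a = displacement_closure_profiles(7)[0]
        b = -shift_profile(a, 1)
        rel = classify_pair(a, b)
        if rel.lag0_value <= -0.8:
            assert rel.relation == "flip"

    def test_unrelated_decoy_is_other(self):
        profiles = displacement_closure_profiles(7)
        for i in range(3):
            assert classify_pair(profiles[i], profiles[3]).relation == "other"
            assert classify_pair(profiles[3], profiles[i]).relation == "other"

    def test_independent_noise_rarely_called_displaced(self):
        # Monte-Carlo null: the window-significance gate keeps chance
        # short-window alignments from qualifying as displacements
        rng = np.random.default_rng(2024)
        n_other = sum(
            classify_pair(rng.normal(size=6), rng.normal(size=6)).relation == "other"
            for _ in range(1000)
        )
        assert n_other >= 900


class TestDetectDisplacements:
    def test_two_neuron_negation_both_flip(self):
        base = displacement_closure_profiles(6)[0]
        rel = detect_displacements(make_model(np.vstack([base, -base]), 1, 2))
        assert rel.relation(1, 2).relation == "flip"
        assert rel.relation(2, 1).relation == "flip"

    def test_constructed_codebook_relations(self):
        profiles = displacement_closure_profiles(7)
        cb = np.vstack([profiles[0], shift_profile(profiles[0], 1), profiles[3]])
        rel = detect_displacements(make_model(cb, 1, 3))
        assert rel.relation(1, 2).relation == "delay"
        assert rel.relation(2, 1).relation == "early"
        assert rel.relation(1, 3).relation == "other"
        for i in (1, 2, 3):
            assert rel.relation(i, i).relation == "conserved"

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_structural_invariants_on_random_models(self, seed):
        rng = np.random.default_rng(seed)
        t = make_table(rng.normal(size=(20, 6)))
        model = train_som(t, GridSize(2, 3), n_epochs=50, seed=seed)
        rel = detect_displacements(model)
        n = model.n_neurons
        for a in range(1, n + 1):
            assert rel.relation(a, a).relation == "conserved"
            for b in range(1, n + 1):
                if a == b:
                    continue
                fwd, back = rel.relation(a, b), rel.relation(b, a)
                assert (fwd.relation == "flip") == (back.relation == "flip")
                if fwd.relation == "delay":
                    assert back.relation == "early"
                    assert back.peak_lag == -fwd.peak_lag


class TestLabelsAndEdges:
    def test_identity_condition_all_conserved(self, pipeline_run):
        # relabel the control itself by faking test columns equal to ref
        mapping = pipeline_run["mapping"]
        labels = pipeline_run["labels"]
        conserved = labels[labels.from_neuron == labels.to_neuron]
        assert (conserved.label == "conserved").all()

    def test_planted_labels_recovered(self, pipeline_run):
        labels = pipeline_run["labels"].set_index("variable_id")["label"]
        truth = pipeline_run["truth"].frame.set_index("variable_id")
        for op, expected in [("flip", "flip"), ("replace", "other")]:
            planted = truth.index[truth.op == op]
            got = labels.reindex(planted)
            want = truth.loc[planted, "expected_label"]
            assert (got == want).all()

    def test_unknown_neuron_in_mapping_rejected(self, pipeline_run):
        import dataclasses
        mapping = pipeline_run["mapping"]
        bad = dataclasses.replace(
            mapping, frame=mapping.frame.assign(test_neuron=999)
        )
        with pytest.raises(KeyError):
            label_variables(bad, pipeline_run["relations"])

    def test_planted_flows_aggregate_exactly(self):
        rows = (
            [{"variable_id": f"a{i}", "condition": "test", "from_neuron": 1,
              "to_neuron": 2, "label": "early"} for i in range(5)]
            + [{"variable_id": f"b{i}", "condition": "test", "from_neuron": 2,
                "to_neuron": 1, "label": "delay"} for i in range(7)]
        )
        table = net_edges(pd.DataFrame(rows), mapping=None)
        assert len(table.edges) == 2
        got = {
            (r.from_neuron, r.to_neuron, r.relation): r.count
            for r in table.edges.itertuples()
        }
        assert got == {(1, 2, "early"): 5, (2, 1, "delay"): 7}
        assert table.conserved_summary["conserved"].tolist() == [0]

    def test_identity_gives_empty_edges_and_full_conserved_summary(self):
        rows = [
            {"variable_id": f"v{i}", "condition": "test", "from_neuron": 1,
             "to_neuron": 1, "label": "conserved"} for i in range(6)
        ]
        table = net_edges(pd.DataFrame(rows), mapping=None)
        assert len(table.edges) == 0
        assert table.conserved_summary["conserved"].tolist() == [6]

    def test_edge_counts_plus_conserved_equal_n(self, pipeline_run):
        table = pipeline_run["edges"]
        n = pipeline_run["mapping"].n_variables
        total = table.edges["count"].sum() + table.conserved_summary["conserved"].sum()
        assert total == n
        assert (table.edges["count"] >= 1).all()

    def test_group_by_splits_counts_without_losing_any(self, pipeline_run):
        table = net_edges(pipeline_run["labels"], pipeline_run["mapping"],
                          group_by="kind")
        plain = pipeline_run["edges"]
        assert table.edges["count"].sum() == plain.edges["count"].sum()
        assert set(table.edges["kind"]) <= {"gene", "phenotype"}

    def test_unknown_group_attribute_rejected(self, pipeline_run):
        with pytest.raises(KeyError, match="nope"):
            net_edges(pipeline_run["labels"], pipeline_run["mapping"],
                      group_by="nope")
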