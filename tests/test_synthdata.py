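import math

import networkx as nx
import numpy as np
import pytest

from perturbgraph.errors import FormatError, ValidationError
from perturbgraph.graphs import InterventionSet
from perturbgraph.synthdata import (ConfounderSpec, InterventionTriplet,
                                    generate_disease_dataset,
                                    generate_treatment_dataset,
                                    inject_confounders, read_dataset,
                                    sample_scm, simulate_state, write_dataset)



def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


class TestSampleScm:
    def test_density_zero_edgeless(self):
        scm = sample_scm(5, 0.0, seed=1)
        assert scm.graph.n_arcs == 0

    def test_seed_determinism(self):
        a, b = sample_scm(12, 0.2, seed=7), sample_scm(12, 0.2, seed=7)
        assert a.graph.arcs == b.graph.arcs
        assert a.weights == b.weights and a.biases == b.biases

    def test_arc_count_within_binomial_bounds(self):
        n, p = 50, 0.1
        scm = sample_scm(n, p, seed=3)
        n_pairs = n * (n - 1) // 2
        mean, sd = n_pairs * p, math.sqrt(n_pairs * p * (1 - p))
        assert abs(scm.graph.n_arcs - mean) < 5 * sd

    def test_weight_and_bias_ranges(self):
        scm = sample_scm(30, 0.2, seed=5)
        for w in scm.weights.values():
            assert 0.5 <= abs(w) <= 2.0
        assert all(-1 <= b <= 1 for b in scm.biases.values())


class TestSimulateState:
    def test_zero_weights_closed_form(self):
        scm = sample_scm(6, 0.0, seed=2, noise_sd=0.0)
        x = simulate_state(scm, noise_seed=0)
        expected = np.array([_logistic(scm.biases[n]) for n in scm.graph.node_ids])
        np.testing.assert_allclose(x, expected, rtol=0, atol=0)

    def test_clamp_overrides_parents(self, chain_scm):
        u = InterventionSet({"b"})
        x = simulate_state(chain_scm, u, {"b": 0.9}, noise_seed=0)
        assert x[chain_scm.graph.node_index("b")] == 0.9

    def test_chain_hand_evaluation(self, chain_scm):
        # a clamped to 1 feeds b through w=2 with bias -1: logistic(1)
        x = simulate_state(chain_scm, InterventionSet({"a"}), {"a": 1.0})
        assert x[chain_scm.graph.node_index("b")] == pytest.approx(
            _logistic(2.0 * 1.0 - 1.0), abs=1e-15)

    def test_noiseless_is_pure_function(self):
        scm = sample_scm(10, 0.3, seed=4, noise_sd=0.0)
        x1 = simulate_state(scm, noise_seed=1)
        x2 = simulate_state(scm, noise_seed=99)  # noise seed irrelevant at sd 0
        np.testing.assert_array_equal(x1, x2)

    def test_clamp_key_mismatch_rejected(self, chain_scm):
        with pytest.raises(ValidationError):
            simulate_state(chain_scm, InterventionSet({"a"}), {"b": 0.5})

    def test_intervention_changes_only_descendants(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            n = int(rng.integers(4, 13))
            scm = sample_scm(n, 0.3, seed=int(rng.integers(2**31)), noise_sd=0.0)
            base = simulate_state(scm)
            v = scm.graph.node_ids[int(rng.integers(n))]
            x = simulate_state(scm, InterventionSet({v}), {v: 0.123})
            dg = scm.graph.to_networkx(directed=True)
            allowed = nx.descendants(dg, v) | {v}
            changed = {scm.graph.node_ids[i] for i in np.nonzero(x != base)[0]}
            assert changed <= allowed


class TestDiseaseDataset:
    def test_noiseless_healthy_states_identical(self):
        scm = sample_scm(8, 0.2, seed=1, noise_sd=0.0)
        u = InterventionSet({scm.graph.node_ids[0]}, "disease")
        data = generate_disease_dataset(scm, u, m=3, seed=2)
        for t in data[1:]:
            np.testing.assert_array_equal(t.x_initial, data[0].x_initial)

    def test_explicit_clamp_values_exact(self):
        scm = sample_scm(8, 0.2, seed=1)
        gene = scm.graph.node_ids[2]
        u = InterventionSet({gene}, "disease")
        data = generate_disease_dataset(scm, u, m=4, seed=2,
                                        clamp_values={gene: 0.0})
        for t in data:
            assert t.x_outcome[scm.graph.node_index(gene)] == 0.0

    def test_byte_identical_rerun(self):
        scm = sample_scm(10, 0.2, seed=1)
        u = InterventionSet({scm.graph.node_ids[1]}, "disease")
        a = generate_disease_dataset(scm, u, m=20, seed=5)
        b = generate_disease_dataset(scm, u, m=20, seed=5)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.x_initial, tb.x_initial)
            np.testing.assert_array_equal(ta.x_outcome, tb.x_outcome)


class TestTreatmentDataset:
    def test_exact_reversal_restores_healthy_state(self):
        scm = sample_scm(10, 0.25, seed=3, noise_sd=0.0)
        x_h = simulate_state(scm)
        genes = list(scm.graph.node_ids[:2])
        disease = InterventionSet(set(genes), "disease")
        library = [InterventionSet(set(genes))]
        clamps = {0: {g: float(x_h[scm.graph.node_index(g)]) for g in genes}}
        data = generate_treatment_dataset(scm, library, 2, seed=4,
                                          disease_genes=disease,
                                          clamp_overrides=clamps)
        for t in data:
            np.testing.assert_allclose(t.x_outcome, x_h, rtol=0, atol=0)

    def test_empty_library_rejected(self):
        scm = sample_scm(5, 0.2, seed=1)
        with pytest.raises(ValidationError):
            generate_treatment_dataset(scm, [], 3, seed=0,
                                       disease_genes=InterventionSet(
                                           {scm.graph.node_ids[0]}, "disease"))

    def test_bookkeeping_counts_and_tags(self):
        scm = sample_scm(12, 0.2, seed=2)
        nodes = scm.graph.node_ids
        disease = InterventionSet({nodes[0]}, "disease")
        lib = [InterventionSet({nodes[i]}) for i in range(1, 11)]
        data = generate_treatment_dataset(scm, lib, 5, seed=6,
                                          disease_genes=disease)
        assert len(data) == 50
        tags = {t.perturbagen_id for t in data}
        assert len(tags) == 10
        for t in data:
            assert t.u.members in {p.members for p in lib}

    def test_unknown_perturbagen_gene_rejected(self):
        scm = sample_scm(5, 0.2, seed=1)
        with pytest.raises(ValidationError):
            generate_treatment_dataset(
                scm, [InterventionSet({"nope"})], 1, seed=0,
                disease_genes=InterventionSet({scm.graph.node_ids[0]}, "disease"))


class TestConfounders:
    def _dataset(self, n_genes=40, m=6, seed=0):
        rng = np.random.default_rng(seed)
        u = InterventionSet({"g0"})
        return [
            InterventionTriplet(rng.uniform(0, 1, n_genes), u,
                                rng.uniform(0, 1, n_genes))
            for _ in range(m)
        ]

    def test_outputs_stay_bounded_and_shaped(self):
        data = self._dataset()
        spec = ConfounderSpec(fraction_perturbed=1.0, n_groups=10,
                              mean_range=(-2, 2), sd_range=(0.5, 1.0), seed=1)
        out = inject_confounders(data, spec)
        assert len(out) == len(data)
        for t_in, t_out in zip(data, out):
            assert t_out.u is t_in.u
            assert np.all((t_out.x_initial >= 0) & (t_out.x_initial <= 1))
            assert np.all((t_out.x_outcome >= 0) & (t_out.x_outcome <= 1))

    def test_degenerate_spec_only_clamps(self):
        data = self._dataset()
        spec = ConfounderSpec(fraction_perturbed=1.0, n_groups=5,
                              mean_range=(0.0, 0.0), sd_range=(1e-12, 1e-12),
                              seed=2)
        out = inject_confounders(data, spec)
        for t_in, t_out in zip(data, out):
            np.testing.assert_allclose(t_out.x_initial, t_in.x_initial, atol=1e-9)

    def test_group_selection_count(self):
        # fraction 0.2 of 50 groups -> exactly 10 groups carry noise
        data = self._dataset(n_genes=200, m=1, seed=3)
        spec = ConfounderSpec(fraction_perturbed=0.2, n_groups=50,
                              mean_range=(5.0, 5.0), sd_range=(1e-9, 1e-9), seed=4)
        out = inject_confounders(data, spec)
        groups = np.array_split(np.arange(200), 50)
        touched = sum(
            1 for idx in groups
            if np.any(out[0].x_initial[idx] != data[0].x_initial[idx])
        )
        assert touched == 10


class TestDatasetIO:
    def test_round_trip_identity(self, tmp_path):
        scm = sample_scm(10, 0.2, seed=1)
        nodes = scm.graph.node_ids
        disease = InterventionSet({nodes[0]}, "disease")
        lib = [InterventionSet({nodes[1], nodes[2]})]
        data = generate_treatment_dataset(scm, lib, 10, seed=2,
                                          disease_genes=disease)
        write_dataset(data, tmp_path / "ds", nodes, {"seed": 2})
        back, manifest = read_dataset(tmp_path / "ds")
        assert manifest["seed"] == 2 and manifest["n_samples"] == 10
        for a, b in zip(data, back):
            np.testing.assert_array_equal(a.x_initial, b.x_initial)
            np.testing.assert_array_equal(a.x_outcome, b.x_outcome)
            assert a.u.members == b.u.members and a.u.kind == b.u.kind
            assert a.perturbagen_id == b.perturbagen_id

    def test_missing_manifest_rejected(self, tmp_path):
        (tmp_path / "ds").mkdir()
        with pytest.raises(FormatError):
            read_dataset(tmp_path / "ds")

    def test_out_of_range_value_rejected(self, tmp_path):
        scm = sample_scm(5, 0.2, seed=1)
        nodes = scm.graph.node_ids
        data = generate_disease_dataset(
            scm, InterventionSet({nodes[0]}, "disease"), m=2, seed=3)
        write_dataset(data, tmp_path / "ds", nodes)
        f = tmp_path / "ds" / "expression_initial.tsv"
        lines = f.read_text().splitlines()
        parts = lines[1].split("\t")
        parts[1] = "1.2"
        lines[1] = "\t".join(parts)
        f.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValidationError):
            read_dataset(tmp_path / "ds")


def test_triplet_validation():
    u = InterventionSet({"a"})
    with pytest.raises(ValidationError):
        InterventionTriplet(np.array([0.5, 1.2]), u, np.array([0.5, 0.5]))
    with pytest.raises(ValidationError):
        InterventionTriplet(np.array([0.5]), u, np.array([0.5, 0.5]))
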