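"""Generator contracts: determinism, planted effects, graph shape, fixture truth."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netcover import synthetic_data as sd
from netcover.errors import ConfigurationError, InputError


class TestExpression:
    def test_no_planted_effect_when_fractions_zero(self, small_config):
        cfg = small_config(frac_up=0.0, frac_down=0.0)
        matrix, truth = sd.generate_expression(cfg)
        assert truth.planted_up == frozenset() and truth.planted_down == frozenset()
        # group means should agree up to sampling noise for every gene
        tumor = matrix.iloc[:, :20].to_numpy().mean()
        normal = matrix.iloc[:, 20:].to_numpy().mean()
        assert tumor == pytest.approx(normal, rel=0.05)

    def test_same_seed_bit_identical(self, small_config):
        cfg = small_config(seed=7)
        m1, t1 = sd.generate_expression(cfg)
        m2, t2 = sd.generate_expression(cfg)
        pd.testing.assert_frame_equal(m1, m2)
        assert t1.planted_up == t2.planted_up

    def test_planted_ratio_near_fold_change(self, small_config):
        # 2^2 = 4 expected tumor/normal mean ratio over planted-up genes;
        # bounds fixed from a seed-panel simulation under this dispersion.
        cfg = small_config(seed=11, frac_down=0.0)
        matrix, truth = sd.generate_expression(cfg)
        up = sorted(truth.planted_up)
        ratio = (
            matrix.loc[up, matrix.columns[:20]].to_numpy().mean()
            / matrix.loc[up, matrix.columns[20:]].to_numpy().mean()
        )
        assert 3.0 <= ratio <= 5.3

    def test_counts_are_nonnegative_integers(self, small_config):
        matrix, _ = sd.generate_expression(small_config())
        assert (matrix.to_numpy() >= 0).all()
        assert np.issubdtype(matrix.to_numpy().dtype, np.integer)

    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_genes", 0),
            ("frac_up", 0.7),  # with frac_down=0.5 violates the sum bound
            ("nb_dispersion", 0.0),
            ("ppi_attach_m", 500),
            ("target_degree_exponent", 1.0),
        ],
    )
    def test_invalid_config_names_field(self, small_config, field, value):
        with pytest.raises(ConfigurationError):
            small_config(**{field: value, "frac_down": 0.5 if field == "frac_up" else 0.05})


class TestPPI:
    def test_attach_one_gives_tree(self):
        cfg = sd.SyntheticConfig(ppi_n_nodes=3, ppi_attach_m=1, seed=0)
        assert len(sd.generate_ppi(cfg)) == 2

    def test_heavy_tailed_degrees(self):
        cfg = sd.SyntheticConfig(ppi_n_nodes=500, ppi_attach_m=2, seed=5)
        edges = sd.generate_ppi(cfg)
        graph = nx.from_pandas_edgelist(edges, "node_a", "node_b")
        degrees = [d for _, d in graph.degree()]
        assert max(degrees) > np.median(degrees)

    @pytest.mark.parametrize("n,m", [(2, 1), (25, 1), (50, 3), (100, 5)])
    def test_simple_connected_graph_contract(self, n, m):
        cfg = sd.SyntheticConfig(ppi_n_nodes=n, ppi_attach_m=m, seed=n + m)
        edges = sd.generate_ppi(cfg)
        assert not (edges["node_a"] == edges["node_b"]).any()
        assert not edges.duplicated(["node_a", "node_b"]).any()
        assert edges["confidence"].between(0, 1).all()
        graph = nx.from_pandas_edgelist(edges, "node_a", "node_b")
        assert nx.is_connected(graph)

    def test_deterministic_per_seed(self):
        cfg = sd.SyntheticConfig(ppi_n_nodes=60, ppi_attach_m=2, seed=9)
        pd.testing.assert_frame_equal(sd.generate_ppi(cfg), sd.generate_ppi(cfg))


class TestDrugTargetMap:
    def test_zero_drugs_empty_map(self):
        cfg = sd.SyntheticConfig(n_drugs=0)
        assert sd.generate_drug_target_map(cfg, ["P1", "P2"]) == {}

    def test_disjoint_case_study_sizes_cover_fifteen(self):
        cfg = sd.SyntheticConfig(n_drugs=6, seed=4)
        result = sd.generate_drug_target_map(
            cfg, [f"P{i}" for i in range(30)], sizes=(2, 3, 1, 5, 2, 2), disjoint=True
        )
        union = set().union(*result.values())
        assert len(union) == 15
        assert sum(len(t) for t in result.values()) == 15

    def test_power_law_sizes(self):
        cfg = sd.SyntheticConfig(n_drugs=50, target_degree_exponent=2.5, seed=3)
        result = sd.generate_drug_target_map(cfg, [f"P{i}" for i in range(200)])
        sizes = [len(t) for t in result.values()]
        assert min(sizes) == 1
        assert np.mean(sizes) < 5

    def test_empty_nodes_errors(self):
        cfg = sd.SyntheticConfig(n_drugs=3)
        with pytest.raises(InputError):
            sd.generate_drug_target_map(cfg, [])


class TestDDI:
    def test_density_extremes(self):
        drugs = [f"D{i}" for i in range(6)]
        none = sd.generate_ddi(drugs, sd.SyntheticConfig(ddi_density=0.0, seed=2))
        assert not any(flag for flag, _ in none.pairs.values())
        full = sd.generate_ddi(drugs, sd.SyntheticConfig(ddi_density=1.0, seed=2))
        assert all(flag for flag, _ in full.pairs.values())
        assert len(full.pairs) == 15

    def test_symmetry_by_construction(self):
        ddi = sd.generate_ddi(list("ABCDEF"), sd.SyntheticConfig(ddi_density=0.5, seed=2))
        for a, b in ddi.pairs:
            assert ddi.interacting(a, b) == ddi.interacting(b, a)

    def test_duplicate_drugs_error(self):
        with pytest.raises(InputError):
            sd.generate_ddi(["A", "A"], sd.SyntheticConfig())


class TestAMLFixture:
    def test_six_drugs_fifteen_disjoint_targets(self, aml_fixture):
        assert len(aml_fixture.drugs) == 6
        assert len(aml_fixture.hubs) == 15
        assert sum(len(t) for t in aml_fixture.drug_targets.values()) == 15

    def test_seven_safe_pairs_reference_fixture_drugs(self, aml_fixture):
        assert len(aml_fixture.safe_pairs) == 7
        for pair in aml_fixture.safe_pairs:
            assert len(pair) == 2
            assert pair <= set(aml_fixture.drugs)

    def test_ddi_covers_all_pairs(self, aml_fixture):
        ddi = aml_fixture.ddi()
        assert len(ddi.pairs) == 15
        safe = {p for p, (flag, _) in ddi.pairs.items() if not flag}
        assert {frozenset(p) for p in safe} == set(aml_fixture.safe_pairs)

    def test_network_counts(self, aml_fixture):
        assert aml_fixture.network_counts == {"total": 404, "druggable": 102}


class TestRoundTrips:
    def test_drug_target_tsv_round_trip(self, tmp_path, aml_fixture):
        path = tmp_path / "dt.tsv"
        sd.write_drug_target_tsv(aml_fixture.drug_targets, path)
        assert sd.read_drug_target_tsv(path) == aml_fixture.drug_targets
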