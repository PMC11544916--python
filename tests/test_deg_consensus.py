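"""Consensus-DE stage: stand-in scorers, strict intersection, locus partition."""

import numpy as np
import pandas as pd
import pytest

from netcover import deg_consensus as dc
from netcover import synthetic_data as sd
from netcover.errors import ConfigurationError, InputError


def _table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "p_adj"])


class TestDEStandins:
    def test_identical_groups_give_zero_lfc(self, small_config):
        matrix, _ = sd.generate_expression(small_config(frac_up=0.0, frac_down=0.0))
        doubled = pd.concat([matrix.iloc[:, :20], matrix.iloc[:, :20]], axis=1)
        doubled.columns = [f"S{i}" for i in range(40)]
        groups = ["tumor"] * 20 + ["normal"] * 20
        table = dc.run_de_standin(doubled, groups, "welch_logcpm")
        assert np.allclose(table["log2fc"], 0.0)

    def test_zero_permutations_rejected(self, small_config):
        matrix, _ = sd.generate_expression(small_config())
        with pytest.raises(InputError):
            dc.run_de_standin(matrix, sd.group_labels(small_config()),
                              "permutation_lfc", n_permutations=0)

    def test_small_group_rejected(self):
        counts = pd.DataFrame(np.ones((5, 3), dtype=int),
                              columns=["a", "b", "c"])
        with pytest.raises(InputError):
            dc.run_de_standin(counts, ["tumor", "normal", "normal"], "welch_logcpm")

    def test_non_integer_counts_rejected(self):
        counts = pd.DataFrame(np.full((3, 4), 1.5), columns=list("abcd"))
        with pytest.raises(InputError):
            dc.run_de_standin(counts, ["tumor"] * 2 + ["normal"] * 2, "welch_logcpm")

    @pytest.mark.parametrize("method", dc.DE_METHODS)
    def test_planted_genes_rank_above_background(self, small_config, method):
        cfg = small_config(seed=11, frac_down=0.0)
        matrix, truth = sd.generate_expression(cfg)
        table = dc.run_de_standin(matrix, sd.group_labels(cfg), method,
                                  n_permutations=300, seed=11)
        planted = table["gene_id"].isin(truth.planted_up)
        assert table.loc[planted, "p_adj"].median() < table.loc[~planted, "p_adj"].median()


class TestConsensus:
    def test_gene_in_all_tables_included(self):
        tables = [_table([("g1", 2.0, 0.01), ("g2", 1.0, 0.5)]) for _ in range(3)]
        assert dc.consensus(tables) == {"g1"}

    def test_gene_in_two_of_three_excluded(self):
        yes = _table([("g1", 2.0, 0.01)])
        no = _table([("g1", 2.0, 0.50)])
        assert dc.consensus([yes, yes, no]) == set()

    def test_direction_down(self):
        tables = [_table([("g1", -2.0, 0.01), ("g2", 2.0, 0.01)])]
        assert dc.consensus(tables, dc.ConsensusConfig(direction="down")) == {"g1"}

    def test_empty_table_list_rejected(self):
        with pytest.raises(InputError):
            dc.consensus([])

    def test_monotone_under_threshold_tightening(self, small_config):
        cfg = small_config(seed=3)
        matrix, _ = sd.generate_expression(cfg)
        tables = [
            dc.run_de_standin(matrix, sd.group_labels(cfg), m, n_permutations=200, seed=3)
            for m in ("welch_logcpm", "ranksum")
        ]
        loose = dc.consensus(tables, dc.ConsensusConfig(q=0.1, lfc_min=0.0))
        tight_q = dc.consensus(tables, dc.ConsensusConfig(q=0.01, lfc_min=0.0))
        tight_lfc = dc.consensus(tables, dc.ConsensusConfig(q=0.1, lfc_min=1.0))
        assert tight_q <= loose and tight_lfc <= loose

    def test_intersection_bounded_by_each_table(self, small_config):
        cfg = small_config(seed=5)
        matrix, _ = sd.generate_expression(cfg)
        tables = [
            dc.run_de_standin(matrix, sd.group_labels(cfg), m, n_permutations=200, seed=5)
            for m in dc.DE_METHODS
        ]
        cfg_c = dc.ConsensusConfig()
        result = dc.consensus(tables, cfg_c)
        for table in tables:
            assert result <= dc.qualifying_set(table, cfg_c)

    def test_recall_of_planted_up(self, small_config):
        cfg = small_config(seed=11)
        matrix, truth = sd.generate_expression(cfg)
        tables = [
            dc.run_de_standin(matrix, sd.group_labels(cfg), m, n_permutations=300, seed=11)
            for m in dc.DE_METHODS
        ]
        result = dc.consensus(tables)
        recall = len(result & truth.planted_up) / len(truth.planted_up)
        assert recall >= 0.8

    @pytest.mark.parametrize("q,lfc", [(0.0, 0.0), (1.5, 0.0), (0.05, -1.0)])
    def test_invalid_config(self, q, lfc):
        with pytest.raises(ConfigurationError):
            dc.ConsensusConfig(q=q, lfc_min=lfc)


class TestLocusPartition:
    def test_empty_gene_set(self):
        annot = pd.DataFrame({"gene_id": ["g1"], "locus_type": ["protein_coding"]})
        counts, pcgs = dc.partition_locus(set(), annot)
        assert counts == {"protein_coding": 0, "ncRNA": 0, "pseudogene": 0, "other": 0}
        assert pcgs == set()

    def test_all_protein_coding(self):
        genes = {f"g{i}" for i in range(10)}
        annot = pd.DataFrame({"gene_id": sorted(genes),
                              "locus_type": ["protein_coding"] * 10})
        counts, pcgs = dc.partition_locus(genes, annot)
        assert counts["protein_coding"] == 10 and pcgs == genes

    def test_mixed_toy_annotation(self):
        # 7 protein-coding / 3 ncRNA / 1 pseudogene / 1 other
        types = ["protein_coding"] * 7 + ["ncRNA"] * 3 + ["pseudogene", "other"]
        genes = [f"g{i}" for i in range(12)]
        annot = pd.DataFrame({"gene_id": genes, "locus_type": types})
        counts, pcgs = dc.partition_locus(set(genes), annot)
        assert counts == {"protein_coding": 7, "ncRNA": 3, "pseudogene": 1, "other": 1}
        assert sum(counts.values()) == 12
        assert len(pcgs) == 7

    def test_missing_gene_counted_as_other_with_warning(self):
        annot = pd.DataFrame({"gene_id": ["g1"], "locus_type": ["protein_coding"]})
        with pytest.warns(UserWarning):
            counts, _ = dc.partition_locus({"g1", "gX"}, annot)
        assert counts["other"] == 1
        assert sum(counts.values()) == 2
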