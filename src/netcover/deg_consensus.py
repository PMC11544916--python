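"""Consensus differential expression across multiple methods, plus locus partition.

A gene makes the consensus list only when *every* method calls it
significant in the same direction — strict intersection. Three lightweight
stand-in scorers (Welch t on log-CPM, rank-sum, permutation on the fold
change) play the role of independent DE methods so the intersection logic is
testable end-to-end on synthetic counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InputError

LOCUS_TYPES = ("protein_coding", "ncRNA", "pseudogene", "other")
DE_METHODS = ("welch_logcpm", "ranksum", "permutation_lfc")


@dataclass(frozen=True)
class ConsensusConfig:
    """Per-table significance thresholds applied before intersecting."""

    q: float = 0.05
    lfc_min: float = 0.0
    direction: str = "up"

    def __post_init__(self) -> None:
        if not 0.0 < self.q <= 1.0:
            raise ConfigurationError(f"q must lie in (0, 1], got {self.q!r}")
        if self.lfc_min < 0:
            raise ConfigurationError(f"lfc_min must be >= 0, got {self.lfc_min!r}")
        if self.direction not in ("up", "down"):
            raise ConfigurationError(f"direction must be 'up' or 'down', got {self.direction!r}")


def _validate_counts(counts: pd.DataFrame, groups: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    if len(groups) != counts.shape[1]:
        raise InputError(
            f"group labels ({len(groups)}) must match sample columns ({counts.shape[1]})"
        )
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values)):
            raise InputError("counts must be nonnegative integers")
        values = values.astype(np.int64)
    if (values < 0).any():
        raise InputError("counts must be nonnegative integers")
    groups = np.asarray(groups)
    tumor = groups == "tumor"
    normal = groups == "normal"
    if tumor.sum() < 2 or normal.sum() < 2:
        raise InputError("each group ('tumor', 'normal') needs at least 2 samples")
    if tumor.sum() + normal.sum() != len(groups):
        raise InputError("group labels must be 'tumor' or 'normal'")
    return tumor, normal


def _cpm(values: np.ndarray) -> np.ndarray:
    libsize = values.sum(axis=0, keepdims=True).astype(float)
    libsize[libsize == 0] = 1.0
    return values / libsize * 1e6


def run_de_standin(
    counts: pd.DataFrame,
    groups: Sequence[str],
    method: str,
    n_permutations: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Score each gene for tumor-vs-normal differential expression.

    Returns a table with columns ``gene_id``, ``log2fc``, ``p_adj`` where the
    fold change is ``log2((mean tumor CPM + 0.5) / (mean normal CPM + 0.5))``
    (the 0.5 pseudocount keeps zero-count genes finite) and ``p_adj`` is the
    Benjamini–Hochberg adjustment of the gene-wise raw p-values.

    Methods: ``welch_logcpm`` (Welch t-test on log2(CPM + 0.5)); ``ranksum``
    (Mann–Whitney with normal approximation and continuity correction);
    ``permutation_lfc`` (two-sided permutation test on the fold change).
    """
    if method not in DE_METHODS:
        raise InputError(f"unknown method {method!r}; choose from {DE_METHODS}")
    tumor, normal = _validate_counts(counts, groups)
    values = counts.to_numpy(dtype=float)
    cpm = _cpm(values)
    mean_t = cpm[:, tumor].mean(axis=1)
    mean_n = cpm[:, normal].mean(axis=1)
    log2fc = np.log2((mean_t + 0.5) / (mean_n + 0.5))

    if method == "welch_logcpm":
        logcpm = np.log2(cpm + 0.5)
        _, pvals = stats.ttest_ind(
            logcpm[:, tumor], logcpm[:, normal], axis=1, equal_var=False
        )
        pvals = np.nan_to_num(pvals, nan=1.0)
    elif method == "ranksum":
        _, pvals = stats.mannwhitneyu(
            cpm[:, tumor], cpm[:, normal], axis=1, alternative="two-sided",
            use_continuity=True, method="asymptotic",
        )
    else:  # permutation_lfc
        if n_permutations < 1:
            raise InputError("permutation_lfc needs n_permutations >= 1")
        rng = np.random.default_rng(seed)
        n_tumor = int(tumor.sum())
        obs = np.abs(log2fc)
        exceed = np.zeros(values.shape[0], dtype=np.int64)
        for _ in range(n_permutations):
            perm = rng.permutation(values.shape[1])
            perm_t = perm[:n_tumor]
            perm_n = perm[n_tumor:]
            m_t = cpm[:, perm_t].mean(axis=1)
            m_n = cpm[:, perm_n].mean(axis=1)
            perm_lfc = np.abs(np.log2((m_t + 0.5) / (m_n + 0.5)))
            exceed += perm_lfc >= obs
        pvals = (1.0 + exceed) / (n_permutations + 1.0)

    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    table = pd.DataFrame(
        {"gene_id": counts.index.astype(str), "log2fc": log2fc, "p_adj": p_adj}
    )
    table.attrs["method_name"] = method
    return table


def qualifying_set(table: pd.DataFrame, cfg: ConsensusConfig) -> set[str]:
    """Genes passing the per-table thresholds in the configured direction."""
    sign_ok = table["log2fc"] > 0 if cfg.direction == "up" else table["log2fc"] < 0
    mask = (table["p_adj"] <= cfg.q) & sign_ok & (table["log2fc"].abs() >= cfg.lfc_min)
    return set(table.loc[mask, "gene_id"])


def consensus(tables: Sequence[pd.DataFrame], cfg: ConsensusConfig | None = None) -> set[str]:
    """Strict intersection of the per-method qualifying sets."""
    if not tables:
        raise InputError("consensus needs at least one DE result table")
    cfg = cfg or ConsensusConfig()
    universes = [set(t["gene_id"]) for t in tables]
    if len(set(map(frozenset, universes))) > 1:
        warnings.warn("DE result tables do not share a gene universe", stacklevel=2)
    result = qualifying_set(tables[0], cfg)
    for table in tables[1:]:
        result &= qualifying_set(table, cfg)
    return result


def partition_locus(
    genes: Iterable[str], annot: pd.DataFrame
) -> tuple[dict[str, int], set[str]]:
    """Count genes per locus type; also return the protein-coding subset.

    Genes missing from the annotation are counted as "other" with a warning.
    """
    if not {"gene_id", "locus_type"}.issubset(annot.columns):
        raise InputError("annotation must have columns ['gene_id', 'locus_type']")
    bad = set(annot["locus_type"]) - set(LOCUS_TYPES)
    if bad:
        raise InputError(f"unknown locus types in annotation: {sorted(bad)}")
    lookup = dict(zip(annot["gene_id"].astype(str), annot["locus_type"]))
    counts = {t: 0 for t in LOCUS_TYPES}
    protein_coding: set[str] = set()
    missing = 0
    for gene in genes:
        locus = lookup.get(gene)
        if locus is None:
            missing += 1
            locus = "other"
        counts[locus] += 1
        if locus == "protein_coding":
            protein_coding.add(gene)
    if missing:
        warnings.warn(f"{missing} genes missing from annotation counted as 'other'",
                      stacklevel=2)
    return counts, protein_coding


# -- TSV dialects -----------------------------------------------------------

def write_de_table_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table[["gene_id", "log2fc", "p_adj"]].to_csv(path, sep="\t", index=False)


def read_de_table_tsv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "log2fc", "p_adj"}.issubset(table.columns):
        raise InputError("DE table must have columns ['gene_id', 'log2fc', 'p_adj']")
    return table


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def read_gene_list(path: str | Path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}
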