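"""Synthetic generators for every pipeline input, plus the AML case-study fixture.

The real study inputs — bulk RNA-seq counts from AML patients versus normal
blood, a STRING-like protein interaction table, a DrugBank-like drug–target
map, and a pairwise drug–drug interaction table — cannot be bundled, so this
module generates stand-ins with the statistical structure the analysis
assumes:

* counts are negative-binomial with log-normal gene means and planted
  up/down-regulated genes at a known log2 fold change;
* the protein–protein interaction (PPI) graph is grown by preferential
  attachment (scale-free, hub-dominated) with Beta-distributed edge
  confidences;
* drug target-set sizes follow a truncated discrete power law;
* the DDI table flags each unordered pair independently at a fixed density.

Every generator is a pure function of its config (including the seed): the
single seed expands into fixed per-component substreams so each component
can be regenerated independently.

The module also packages the published AML case study: six approved drugs
(procaine, amiodarone, vismodegib, fostamatinib, artenimol, ponatinib),
the 15 network hubs they target, and the seven interaction-free pairs
reported for them. This small, fully printed table is the ground truth the
test suite checks the selector and enumerator against.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .combo_enumerator import DDIMatrix
from .errors import ConfigurationError, InputError

# Fixed substream offsets: component i draws from default_rng([seed, offset]).
_STREAMS = {"expression": 0, "graph": 1, "drugs": 2, "ddi": 3, "annotation": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-shaped defaults for all synthetic inputs.

    Sample sizes mirror the AML cohort design (151 tumor vs 456 normal blood
    samples); ~7.5% of genes are planted up-regulated (about 1500 of 20000),
    the PPI graph has one node per upregulated protein-coding gene candidate,
    and 607 drugs draw power-law-sized target sets.
    """

    n_genes: int = 20_000
    n_samples_tumor: int = 151
    n_samples_normal: int = 456
    frac_up: float = 0.075
    frac_down: float = 0.075
    planted_lfc: float = 2.0
    nb_dispersion: float = 0.2
    ppi_n_nodes: int = 1233
    ppi_attach_m: int = 3
    conf_beta_a: float = 8.0
    conf_beta_b: float = 2.0
    n_drugs: int = 607
    target_degree_exponent: float = 2.5
    ddi_density: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        positive_ints = {
            "n_genes": self.n_genes,
            "n_samples_tumor": self.n_samples_tumor,
            "n_samples_normal": self.n_samples_normal,
            "ppi_n_nodes": self.ppi_n_nodes,
        }
        for name, value in positive_ints.items():
            if not isinstance(value, (int, np.integer)) or value <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        for name, value in (("frac_up", self.frac_up), ("frac_down", self.frac_down),
                            ("ddi_density", self.ddi_density)):
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")
        if self.frac_up + self.frac_down > 1.0:
            raise ConfigurationError(
                f"frac_up + frac_down must be <= 1, got {self.frac_up + self.frac_down}"
            )
        if self.nb_dispersion <= 0:
            raise ConfigurationError(f"nb_dispersion must be > 0, got {self.nb_dispersion!r}")
        if self.ppi_attach_m < 1:
            raise ConfigurationError(f"ppi_attach_m must be >= 1, got {self.ppi_attach_m!r}")
        if self.ppi_attach_m >= self.ppi_n_nodes:
            raise ConfigurationError(
                f"ppi_attach_m must be < ppi_n_nodes, got {self.ppi_attach_m} >= {self.ppi_n_nodes}"
            )
        if self.conf_beta_a <= 0 or self.conf_beta_b <= 0:
            raise ConfigurationError("conf_beta_a and conf_beta_b must be > 0")
        if self.n_drugs < 0:
            raise ConfigurationError(f"n_drugs must be >= 0, got {self.n_drugs!r}")
        if self.target_degree_exponent <= 1:
            raise ConfigurationError(
                f"target_degree_exponent must be > 1, got {self.target_degree_exponent!r}"
            )


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth recorded alongside each generated dataset."""

    planted_up: frozenset[str]
    planted_down: frozenset[str]
    drug_targets_truth: dict[str, frozenset[str]] = field(default_factory=dict)
    safe_pairs_truth: frozenset[frozenset[str]] = frozenset()


# ---------------------------------------------------------------------------
# Expression counts
# ---------------------------------------------------------------------------

def generate_expression(config: SyntheticConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Negative-binomial count matrix (genes x samples) with planted DE genes.

    Gene baseline means are log-normal; planted up-regulated genes have their
    tumor-group mean multiplied by 2**planted_lfc (down-regulated: divided).
    Counts are drawn as a gamma–Poisson mixture so that
    ``var = mu + nb_dispersion * mu**2``.
    """
    rng = _rng(config.seed, "expression")
    n_genes = config.n_genes
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"T{i:03d}" for i in range(config.n_samples_tumor)] + [
        f"N{i:03d}" for i in range(config.n_samples_normal)
    ]

    base_mean = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=n_genes)

    n_up = int(round(config.frac_up * n_genes))
    n_down = int(round(config.frac_down * n_genes))
    order = rng.permutation(n_genes)
    up_idx = order[:n_up]
    down_idx = order[n_up:n_up + n_down]

    fold = 2.0 ** config.planted_lfc
    tumor_mean = base_mean.copy()
    tumor_mean[up_idx] *= fold
    tumor_mean[down_idx] /= fold

    def _draw(mu: np.ndarray, n_samples: int) -> np.ndarray:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape=shape, scale=mu[:, None] * config.nb_dispersion,
                        size=(n_genes, n_samples))
        return rng.poisson(lam)

    counts = np.concatenate(
        [_draw(tumor_mean, config.n_samples_tumor), _draw(base_mean, config.n_samples_normal)],
        axis=1,
    )
    matrix = pd.DataFrame(counts, index=genes, columns=samples, dtype=np.int64)
    truth = SyntheticTruth(
        planted_up=frozenset(genes[i] for i in up_idx),
        planted_down=frozenset(genes[i] for i in down_idx),
    )
    return matrix, truth


def group_labels(config: SyntheticConfig) -> list[str]:
    """Column-aligned group labels for a matrix from :func:`generate_expression`."""
    return ["tumor"] * config.n_samples_tumor + ["normal"] * config.n_samples_normal


def generate_annotation(
    gene_ids: Sequence[str],
    config: SyntheticConfig,
    fractions: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Assign a locus type to every gene (protein_coding / ncRNA / pseudogene / other).

    Default mix follows the rough composition of an upregulated-DEG list in a
    leukemia cohort: mostly protein-coding with a minority of non-coding loci.
    """
    fractions = dict(fractions or {"protein_coding": 0.80, "ncRNA": 0.15,
                                   "pseudogene": 0.04, "other": 0.01})
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise InputError("locus-type fractions must sum to 1")
    rng = _rng(config.seed, "annotation")
    types = rng.choice(list(fractions), p=list(fractions.values()), size=len(gene_ids))
    return pd.DataFrame({"gene_id": list(gene_ids), "locus_type": types})


# ---------------------------------------------------------------------------
# PPI graph
# ---------------------------------------------------------------------------

def generate_ppi(
    config: SyntheticConfig, node_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Scale-free PPI edge list with Beta-distributed confidences.

    The graph is grown by preferential attachment from a path on the first
    ``ppi_attach_m`` nodes, so it is connected, simple, and heavy-tailed in
    degree. Each edge carries an independent Beta(conf_beta_a, conf_beta_b)
    confidence in [0, 1].
    """
    n, m = config.ppi_n_nodes, config.ppi_attach_m
    if n < 2:
        raise ConfigurationError(f"ppi_n_nodes must be >= 2, got {n}")
    rng = _rng(config.seed, "graph")
    graph_seed = int(rng.integers(0, 2**31 - 1))
    # Seed graph: a path on max(m, 2) nodes (m=1 still needs one edge so the
    # attachment pool is nonempty).
    graph = nx.barabasi_albert_graph(n, m, seed=graph_seed,
                                     initial_graph=nx.path_graph(max(m, 2)))
    if node_ids is None:
        node_ids = [f"P{i:05d}" for i in range(n)]
    else:
        node_ids = list(node_ids)
        if len(node_ids) < n:
            raise InputError(
                f"need at least {n} node ids for the PPI graph, got {len(node_ids)}"
            )
    edges = sorted(tuple(sorted(e)) for e in graph.edges())
    conf = rng.beta(config.conf_beta_a, config.conf_beta_b, size=len(edges))
    return pd.DataFrame(
        {
            "node_a": [node_ids[a] for a, _ in edges],
            "node_b": [node_ids[b] for _, b in edges],
            "confidence": conf,
        }
    )


# ---------------------------------------------------------------------------
# Drug–target map and DDI
# ---------------------------------------------------------------------------

def _power_law_sizes(
    n_drugs: int, exponent: float, max_size: int, rng: np.random.Generator
) -> np.ndarray:
    sizes = np.arange(1, max_size + 1, dtype=float)
    weights = sizes ** (-exponent)
    weights /= weights.sum()
    return rng.choice(np.arange(1, max_size + 1), p=weights, size=n_drugs)


def generate_drug_target_map(
    config: SyntheticConfig,
    node_ids: Sequence[str],
    sizes: Sequence[int] | None = None,
    disjoint: bool = False,
) -> dict[str, frozenset[str]]:
    """Drug → target-set map with power-law target-set sizes.

    ``sizes`` overrides the sampled sizes (one per drug); ``disjoint`` draws
    target sets without overlap across drugs, which is the regime of the
    packaged case study (each hub has exactly one targeting drug).
    """
    if config.n_drugs == 0 and sizes is None:
        return {}
    node_ids = list(node_ids)
    if not node_ids:
        raise InputError("node_ids must be nonempty when drugs are requested")
    rng = _rng(config.seed, "drugs")
    n_drugs = len(sizes) if sizes is not None else config.n_drugs
    if sizes is None:
        sizes = _power_law_sizes(n_drugs, config.target_degree_exponent,
                                 len(node_ids), rng)
    sizes = [int(s) for s in sizes]
    if any(s < 1 for s in sizes):
        raise InputError("every drug needs at least one target")
    drug_ids = [f"D{i:04d}" for i in range(n_drugs)]
    result: dict[str, frozenset[str]] = {}
    if disjoint:
        if sum(sizes) > len(node_ids):
            raise InputError(
                f"disjoint target sets need {sum(sizes)} nodes but only "
                f"{len(node_ids)} are available"
            )
        pool = list(rng.permutation(node_ids))
        cursor = 0
        for drug, s in zip(drug_ids, sizes):
            result[drug] = frozenset(pool[cursor:cursor + s])
            cursor += s
    else:
        for drug, s in zip(drug_ids, sizes):
            s = min(s, len(node_ids))
            result[drug] = frozenset(rng.choice(node_ids, size=s, replace=False))
    return result


def generate_ddi(drug_ids: Sequence[str], config: SyntheticConfig) -> DDIMatrix:
    """Flag each unordered drug pair as interacting with probability ddi_density."""
    drugs = list(drug_ids)
    if len(set(drugs)) != len(drugs):
        raise InputError("drug_ids must be distinct")
    rng = _rng(config.seed, "ddi")
    ddi = DDIMatrix()
    for i in range(len(drugs)):
        for j in range(i + 1, len(drugs)):
            interacting = bool(rng.random() < config.ddi_density)
            severity = (
                str(rng.choice(["minor", "moderate", "major"]))
                if interacting
                else "unspecified"
            )
            ddi.set_pair(drugs[i], drugs[j], interacting, severity)
    return ddi


# ---------------------------------------------------------------------------
# The AML case-study fixture
# ---------------------------------------------------------------------------

_AML_DRUG_TARGETS: dict[str, frozenset[str]] = {
    "procaine": frozenset({"DNMT1", "DNMT3A"}),
    "amiodarone": frozenset({"PPARA", "CACNB2", "CACNB4"}),
    "vismodegib": frozenset({"SMO"}),
    "fostamatinib": frozenset({"INSR", "WEE1", "KIT", "PLK1", "PLK4"}),
    "artenimol": frozenset({"FLNA", "RPS8"}),
    "ponatinib": frozenset({"ABL1", "RET"}),
}

_AML_SAFE_PAIRS: frozenset[frozenset[str]] = frozenset(
    frozenset(p)
    for p in [
        ("vismodegib", "fostamatinib"),
        ("vismodegib", "amiodarone"),
        ("vismodegib", "artenimol"),
        ("procaine", "fostamatinib"),
        ("procaine", "ponatinib"),
        ("artenimol", "amiodarone"),
        ("artenimol", "fostamatinib"),
    ]
)


@dataclass(frozen=True)
class AMLFixture:
    """The published AML case study: 6 drugs, their 15 hub targets, 7 safe pairs.

    ``network_counts`` records the reported AML-network node tallies
    (404 total, 102 druggable) used by the druggability arithmetic checks.
    """

    drug_targets: dict[str, frozenset[str]]
    safe_pairs: frozenset[frozenset[str]]
    network_counts: dict[str, int]

    @property
    def drugs(self) -> list[str]:
        return sorted(self.drug_targets)

    @property
    def hubs(self) -> frozenset[str]:
        out: set[str] = set()
        for targets in self.drug_targets.values():
            out |= targets
        return frozenset(out)

    def ddi(self) -> DDIMatrix:
        """Binary DDI table: every non-safe pair of the 6 drugs is interacting."""
        ddi = DDIMatrix()
        drugs = self.drugs
        for i in range(len(drugs)):
            for j in range(i + 1, len(drugs)):
                pair = frozenset({drugs[i], drugs[j]})
                ddi.set_pair(drugs[i], drugs[j],
                             interacting=pair not in self.safe_pairs,
                             severity="unspecified")
        return ddi


def load_aml_fixture() -> AMLFixture:
    """Load the hard-coded AML case-study fixture."""
    return AMLFixture(
        drug_targets=dict(_AML_DRUG_TARGETS),
        safe_pairs=_AML_SAFE_PAIRS,
        network_counts={"total": 404, "druggable": 102},
    )


# ---------------------------------------------------------------------------
# Writers (plain TSV/JSON dialects shared across the pipeline)
# ---------------------------------------------------------------------------

def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def write_edges_tsv(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_drug_target_tsv(drug_targets: Mapping[str, frozenset[str]], path: str | Path) -> None:
    rows = [
        {"drug": drug, "target": target}
        for drug in sorted(drug_targets)
        for target in sorted(drug_targets[drug])
    ]
    pd.DataFrame(rows, columns=["drug", "target"]).to_csv(path, sep="\t", index=False)


def read_drug_target_tsv(path: str | Path) -> dict[str, frozenset[str]]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"drug", "target"}.issubset(frame.columns):
        raise InputError("drug–target table must have columns ['drug', 'target']")
    out: dict[str, set[str]] = {}
    for row in frame.itertuples(index=False):
        out.setdefault(row.drug, set()).add(row.target)
    return {drug: frozenset(targets) for drug, targets in out.items()}


def write_truth_json(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "planted_up": sorted(truth.planted_up),
        "planted_down": sorted(truth.planted_down),
        "drug_targets_truth": {d: sorted(t) for d, t in truth.drug_targets_truth.items()},
        "safe_pairs_truth": sorted(sorted(p) for p in truth.safe_pairs_truth),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def config_to_dict(config: SyntheticConfig) -> dict:
    return dataclasses.asdict(config)
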