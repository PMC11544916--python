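"""End-to-end orchestration: data -> consensus -> network -> selection -> combos.

The pipeline can run in three modes:

* ``fixture`` — the packaged AML case study (6 drugs / 15 hubs / 7 safe
  pairs) is pushed through the selector and the combination enumerator;
* ``synthetic`` — all inputs are generated from a :class:`SyntheticConfig`
  and the full chain runs: three DE stand-ins, consensus of upregulated
  genes, locus partition, confidence-filtered PPI network, druggability
  split, greedy drug selection, and DDI-constrained combination reports;
* ``files`` — the same chain on user-supplied TSV tables.

Every run writes its stage outputs, a ``report.json`` with mutually
consistent stage counts and input/output checksums, and a separate
``timings.json`` (kept out of report.json so reruns with the same seed are
bit-identical).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from . import combo_enumerator as ce
from . import deg_consensus as dc
from . import druggability as dg
from . import greedy_selector as gs
from . import network_build as nb
from . import synthetic_data as sd
from .errors import ConfigurationError, NetcoverError

logger = logging.getLogger("netcover")


class StageError(NetcoverError):
    """A pipeline stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class InputPaths:
    """File-mode inputs; any table may be None if its stage is skipped."""

    de_tables: tuple[str, ...] = ()
    annotation: str | None = None
    edges: str | None = None
    drug_targets: str | None = None
    ddi: str | None = None


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # synthetic | fixture | files
    synthetic: sd.SyntheticConfig | None = None
    inputs: InputPaths | None = None
    consensus: dc.ConsensusConfig = field(default_factory=dc.ConsensusConfig)
    network: nb.NetworkConfig = field(default_factory=nb.NetworkConfig)
    greedy: gs.GreedyConfig = field(default_factory=gs.GreedyConfig)
    combo_ks: tuple[int, ...] = (2, 3)
    outdir: str = "netcover_out"
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "fixture", "files"):
            raise ConfigurationError(f"mode must be synthetic|fixture|files, got {self.mode!r}")
        if self.mode == "synthetic":
            if self.inputs is not None:
                raise ConfigurationError("synthetic mode takes no input paths")
            if self.synthetic is None:
                self.synthetic = sd.SyntheticConfig()
            if self.seed is not None:
                self.synthetic = dataclasses.replace(self.synthetic, seed=self.seed)
            self.seed = self.synthetic.seed
        elif self.mode == "files":
            if self.inputs is None:
                raise ConfigurationError("files mode requires input paths")
            if self.synthetic is not None:
                raise ConfigurationError("files mode takes no synthetic config")


@dataclass
class RunReport:
    mode: str
    version: str
    seed: int | None
    consensus_size: int = 0
    locus_partition: dict[str, int] = field(default_factory=dict)
    network_nodes: int = 0
    network_edges: int = 0
    n_druggable: int = 0
    n_undruggable: int = 0
    pct_undruggable: float = 0.0
    n_unique_drugs: int = 0
    selected_drugs: list[str] = field(default_factory=list)
    covered_hubs: int = 0
    safe_pair_count: int = 0
    safe_triple_count: int = 0
    config_echo: dict = field(default_factory=dict)
    output_checksums: dict[str, str] = field(default_factory=dict)
    wall_clock: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.network_nodes:
            assert self.n_druggable + self.n_undruggable == self.network_nodes

    def to_dict(self, include_timings: bool = False) -> dict:
        out = dataclasses.asdict(self)
        if not include_timings:
            out.pop("wall_clock")
        return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_echo(cfg: PipelineConfig) -> dict:
    echo = {
        "mode": cfg.mode,
        "consensus": dataclasses.asdict(cfg.consensus),
        "network": dataclasses.asdict(cfg.network),
        "greedy": dataclasses.asdict(cfg.greedy),
        "combo_ks": list(cfg.combo_ks),
        "seed": cfg.seed,
    }
    if cfg.synthetic is not None:
        echo["synthetic"] = dataclasses.asdict(cfg.synthetic)
    if cfg.inputs is not None:
        echo["inputs"] = dataclasses.asdict(cfg.inputs)
    return echo


def run(cfg: PipelineConfig) -> RunReport:
    """Execute the configured stages; write outputs + report under cfg.outdir."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stale_marker = outdir / "_STALE"
    stale_marker.write_text("run in progress; outputs incomplete\n")

    report = RunReport(mode=cfg.mode, version=__version__, seed=cfg.seed,
                       config_echo=_config_echo(cfg))
    written: list[Path] = []

    def _stage(name: str):
        class _Timer:
            def __enter__(self) -> None:
                logger.info("stage %s: start", name)
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb) -> bool:
                report.wall_clock[name] = time.perf_counter() - self.t0
                if exc is not None:
                    raise StageError(name, exc) from exc
                logger.info("stage %s: done in %.3fs", name, report.wall_clock[name])
                return False

        return _Timer()

    if cfg.mode == "fixture":
        fixture = sd.load_aml_fixture()
        with _stage("selection"):
            scores = gs.uniform_scores(sorted(fixture.hubs))
            selection = gs.greedy_select(scores, fixture.drug_targets,
                                         gs.GreedyConfig(alpha=0.0))
            report.selected_drugs = list(selection.selected_drugs)
            report.covered_hubs = len(selection.covered)
            gs.write_selection_json(selection, outdir / "selection.json")
            written.append(outdir / "selection.json")
        with _stage("druggability"):
            counts = fixture.network_counts
            drept = dg.report_from_counts(counts["total"], counts["druggable"])
            report.network_nodes = drept.n_total
            report.n_druggable = drept.n_druggable
            report.n_undruggable = drept.n_undruggable
            report.pct_undruggable = drept.pct_undruggable
            report.n_unique_drugs = len(fixture.drugs)
            dg.write_report_json(drept, outdir / "druggability.json")
            written.append(outdir / "druggability.json")
        with _stage("combos"):
            ddi = fixture.ddi()
            for k in cfg.combo_ks:
                reports = ce.enumerate_combos(fixture.drugs, fixture.drug_targets, ddi, k)
                n_safe = sum(r.safe for r in reports)
                if k == 2:
                    report.safe_pair_count = n_safe
                elif k == 3:
                    report.safe_triple_count = n_safe
                ce.write_reports_tsv(reports, outdir / f"combos_k{k}.tsv")
                written.append(outdir / f"combos_k{k}.tsv")
    else:
        # synthetic or files: full chain
        with _stage("inputs"):
            if cfg.mode == "synthetic":
                syn = cfg.synthetic
                assert syn is not None
                if syn.ppi_n_nodes > syn.n_genes:
                    raise ConfigurationError(
                        "ppi_n_nodes must be <= n_genes so PPI nodes map onto genes"
                    )
                matrix, _truth = sd.generate_expression(syn)
                groups = sd.group_labels(syn)
                annot = sd.generate_annotation(list(matrix.index), syn)
                edges = sd.generate_ppi(syn, node_ids=list(matrix.index))
                drug_targets = sd.generate_drug_target_map(
                    syn, node_ids=list(matrix.index[: syn.ppi_n_nodes])
                )
                ddi = sd.generate_ddi(sorted(drug_targets), syn)
                tables = [
                    dc.run_de_standin(matrix, groups, method, seed=syn.seed)
                    for method in dc.DE_METHODS
                ]
            else:
                # files mode: only the DE tables and annotation load here;
                # each later table loads inside its own stage so a missing
                # file aborts with that stage's name.
                paths = cfg.inputs
                assert paths is not None
                tables = [dc.read_de_table_tsv(p) for p in paths.de_tables]
                annot = (
                    dc.pd.read_csv(paths.annotation, sep="\t", dtype=str)
                    if paths.annotation
                    else None
                )
                edges = drug_targets = None
                ddi = None

        with _stage("consensus"):
            up_genes = dc.consensus(tables, cfg.consensus)
            report.consensus_size = len(up_genes)
            dc.write_gene_list(up_genes, outdir / "consensus_up.txt")
            written.append(outdir / "consensus_up.txt")

        with _stage("locus_partition"):
            if annot is not None:
                locus_counts, pcgs = dc.partition_locus(up_genes, annot)
            else:
                locus_counts, pcgs = {}, set(up_genes)
            report.locus_partition = locus_counts

        with _stage("network"):
            if cfg.mode == "files":
                if not cfg.inputs.edges:
                    raise NetcoverError("no PPI edge table supplied")
                edges = nb.read_edges_tsv(cfg.inputs.edges)
            if edges is None:
                raise NetcoverError("no PPI edge table supplied")
            net = nb.build_network(edges, keep_nodes=pcgs, cfg=cfg.network)
            report.network_nodes = net.number_of_nodes()
            report.network_edges = net.number_of_edges()
            nb.write_network_tsv(net, outdir / "network.tsv")
            nb.write_graphml(net, outdir / "network.graphml")
            written += [outdir / "network.tsv", outdir / "network.graphml"]
            stats = nb.node_stats(net) if net.number_of_nodes() else None
            if stats is not None:
                nb.write_node_stats_tsv(stats, outdir / "node_stats.tsv")
                written.append(outdir / "node_stats.tsv")

        with _stage("druggability"):
            if cfg.mode == "files":
                if not cfg.inputs.drug_targets:
                    raise NetcoverError("no drug–target table supplied")
                drug_targets = sd.read_drug_target_tsv(cfg.inputs.drug_targets)
            if drug_targets is None:
                raise NetcoverError("no drug–target table supplied")
            if report.network_nodes:
                drept, flags = dg.classify(net, drug_targets)
                report.n_druggable = drept.n_druggable
                report.n_undruggable = drept.n_undruggable
                report.pct_undruggable = drept.pct_undruggable
                report.n_unique_drugs = drept.n_unique_drugs
                dg.write_report_json(drept, outdir / "druggability.json")
                dg.write_flags_tsv(flags, outdir / "druggability_flags.tsv")
                written += [outdir / "druggability.json", outdir / "druggability_flags.tsv"]

        with _stage("selection"):
            if report.network_nodes and stats is not None:
                scores = gs.protein_score(stats, cfg.greedy)
                network_map = {
                    drug: frozenset(t for t in targets if t in scores)
                    for drug, targets in drug_targets.items()
                }
                network_map = {d: t for d, t in network_map.items() if t}
                selection = gs.greedy_select(scores, network_map, cfg.greedy)
                report.selected_drugs = list(selection.selected_drugs)
                report.covered_hubs = len(selection.covered)
                gs.write_selection_json(selection, outdir / "selection.json")
                written.append(outdir / "selection.json")
            else:
                selection = None

        with _stage("combos"):
            if cfg.mode == "files" and ddi is None:
                ddi = ce.read_ddi_tsv(cfg.inputs.ddi) if cfg.inputs.ddi else ce.DDIMatrix()
            if selection is not None and len(selection.selected_drugs) >= 2:
                pool = sorted(selection.selected_drugs)
                for k in cfg.combo_ks:
                    if len(pool) < k:
                        continue
                    reports = ce.enumerate_combos(pool, drug_targets, ddi, k)
                    n_safe = sum(r.safe for r in reports)
                    if k == 2:
                        report.safe_pair_count = n_safe
                    elif k == 3:
                        report.safe_triple_count = n_safe
                    ce.write_reports_tsv(reports, outdir / f"combos_k{k}.tsv")
                    written.append(outdir / f"combos_k{k}.tsv")

    report.validate()
    report.output_checksums = {p.name: _sha256(p) for p in written}
    (outdir / "report.json").write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    (outdir / "timings.json").write_text(json.dumps(report.wall_clock, indent=2))
    stale_marker.unlink(missing_ok=True)
    return report


def run_fixture(outdir: str | Path = "netcover_out") -> RunReport:
    """Convenience wrapper: run the packaged AML case study end to end."""
    return run(PipelineConfig(mode="fixture", outdir=str(outdir)))
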