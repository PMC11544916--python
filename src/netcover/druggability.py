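"""Partition network nodes into druggable and undruggable.

A node is druggable when at least one known drug lists it among its
targets. The report mirrors the tallies a network-pharmacology survey
prints: total nodes, druggable/undruggable counts, the undruggable
percentage (half-up, 2 decimals), and the number of distinct drugs hitting
at least one node of the network.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import InputError


@dataclass(frozen=True)
class DruggabilityReport:
    n_total: int
    n_druggable: int
    n_undruggable: int
    pct_undruggable: float
    n_unique_drugs: int


def _round_half_up(value: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(value)).quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))


def classify(
    net: nx.Graph | Iterable[str],
    drug_targets: Mapping[str, frozenset[str] | set[str]],
) -> tuple[DruggabilityReport, dict[str, bool]]:
    """Flag each network node as druggable and summarize the partition.

    Drugs whose targets all fall outside the network do not count toward
    ``n_unique_drugs`` — the drug tally is network-relative.
    """
    nodes = set(net.nodes()) if isinstance(net, nx.Graph) else set(net)
    if not nodes:
        raise InputError("cannot classify an empty network")
    targeted: set[str] = set()
    relevant_drugs: set[str] = set()
    for drug, targets in drug_targets.items():
        hit = set(targets) & nodes
        if hit:
            targeted |= hit
            relevant_drugs.add(drug)
    flags = {node: node in targeted for node in sorted(nodes)}
    n_total = len(nodes)
    n_druggable = len(targeted)
    n_undruggable = n_total - n_druggable
    report = DruggabilityReport(
        n_total=n_total,
        n_druggable=n_druggable,
        n_undruggable=n_undruggable,
        pct_undruggable=_round_half_up(100.0 * n_undruggable / n_total),
        n_unique_drugs=len(relevant_drugs),
    )
    return report, flags


def report_from_counts(n_total: int, n_druggable: int) -> DruggabilityReport:
    """Druggability arithmetic from printed counts alone (no drug identities)."""
    if n_total <= 0 or not 0 <= n_druggable <= n_total:
        raise InputError(
            f"need 0 <= n_druggable <= n_total with n_total > 0, got {n_druggable}/{n_total}"
        )
    n_undruggable = n_total - n_druggable
    return DruggabilityReport(
        n_total=n_total,
        n_druggable=n_druggable,
        n_undruggable=n_undruggable,
        pct_undruggable=_round_half_up(100.0 * n_undruggable / n_total),
        n_unique_drugs=0,
    )


def write_report_json(report: DruggabilityReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(report), indent=2))


def write_flags_tsv(flags: Mapping[str, bool], path: str | Path) -> None:
    frame = pd.DataFrame(
        {"node": list(flags), "druggable": [int(v) for v in flags.values()]}
    )
    frame.to_csv(path, sep="\t", index=False)
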