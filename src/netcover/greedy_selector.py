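"""Greedy minimal-drug / maximal-hub-coverage selection.

The selector treats each drug as a set of network proteins and greedily
picks, at every iteration, the drug whose not-yet-covered targets carry the
largest total protein score. With uniform scores (alpha = 0) this is the
classic greedy maximum-coverage / set-cover heuristic, which guarantees at
least a (1 - 1/e) fraction of the optimal coverage at any fixed budget;
with alpha = 1 the score is the normalized network degree, steering the
selection toward hubs. A brute-force oracle over all k-subsets is provided
for verification at small scale.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, InputError


@dataclass(frozen=True)
class GreedyConfig:
    """Selection knobs.

    ``alpha`` blends connectivity into the protein score:
    score(p) = alpha * hub_score(p) + (1 - alpha), so alpha=1 weights
    proteins purely by normalized degree and alpha=0 makes every protein
    worth 1 (plain maximum coverage). ``budget=None`` means unlimited
    (greedy runs to zero marginal gain, i.e., greedy weighted set cover).
    ``hub_pool='top_q'`` restricts coverage credit to the top ``top_q``
    quantile of proteins by score.
    """

    alpha: float = 1.0
    budget: int | None = None
    min_gain: float = 0.0
    hub_pool: str = "all_druggable"
    top_q: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError(f"alpha must lie in [0, 1], got {self.alpha!r}")
        if self.budget is not None and self.budget < 1:
            raise ConfigurationError(f"budget must be >= 1 or None, got {self.budget!r}")
        if self.min_gain < 0:
            raise ConfigurationError(f"min_gain must be >= 0, got {self.min_gain!r}")
        if self.hub_pool not in ("all_druggable", "top_q"):
            raise ConfigurationError(
                f"hub_pool must be 'all_druggable' or 'top_q', got {self.hub_pool!r}"
            )
        if not 0.0 < self.top_q <= 1.0:
            raise ConfigurationError(f"top_q must lie in (0, 1], got {self.top_q!r}")


@dataclass(frozen=True)
class SelectionResult:
    selected_drugs: tuple[str, ...]
    covered: frozenset[str]
    trajectory: tuple[tuple[str, float, int], ...]  # (drug, marginal_gain, cum covered count)
    protein_scores: dict[str, float] = field(default_factory=dict)


def protein_score(stats: pd.DataFrame, cfg: GreedyConfig | None = None) -> dict[str, float]:
    """Score each protein as alpha * hub_score + (1 - alpha); always in (0, 1]."""
    cfg = cfg or GreedyConfig()
    if len(stats) == 0:
        raise InputError("node stats must be nonempty")
    return {
        str(node): cfg.alpha * float(hub) + (1.0 - cfg.alpha)
        for node, hub in zip(stats["node"], stats["hub_score"])
    }


def uniform_scores(proteins: Sequence[str]) -> dict[str, float]:
    """Unit score per protein — plain (unweighted) maximum coverage."""
    return {str(p): 1.0 for p in proteins}


def _pool(scores: Mapping[str, float], cfg: GreedyConfig) -> set[str]:
    if cfg.hub_pool == "all_druggable":
        return set(scores)
    n_keep = max(1, math.ceil(cfg.top_q * len(scores)))
    ranked = sorted(scores.items(), key=lambda t: (-t[1], t[0]))
    return {p for p, _ in ranked[:n_keep]}


def greedy_select(
    scores: Mapping[str, float],
    drug_targets: Mapping[str, frozenset[str] | set[str]],
    cfg: GreedyConfig | None = None,
) -> SelectionResult:
    """Iteratively pick the drug with the largest marginal covered score.

    Stops when the budget is exhausted or the best marginal gain drops below
    ``min_gain`` (or to zero). Ties break toward the drug with fewer total
    targets, then by lexicographic drug id, so the result is independent of
    input order.
    """
    cfg = cfg or GreedyConfig()
    if not drug_targets:
        warnings.warn("empty drug–target map: nothing to select", stacklevel=2)
        return SelectionResult((), frozenset(), (), dict(scores))
    pool = _pool(scores, cfg)
    in_pool_targets = {
        drug: frozenset(t for t in targets if t in pool)
        for drug, targets in drug_targets.items()
    }
    total_sizes = {drug: len(targets) for drug, targets in drug_targets.items()}

    selected: list[str] = []
    covered: set[str] = set()
    trajectory: list[tuple[str, float, int]] = []
    remaining = set(drug_targets)
    while remaining:
        if cfg.budget is not None and len(selected) >= cfg.budget:
            break
        best: tuple[float, int, str] | None = None
        for drug in remaining:
            gain = sum(scores[p] for p in in_pool_targets[drug] if p not in covered)
            key = (-gain, total_sizes[drug], drug)
            if best is None or key < best:
                best = key
        assert best is not None
        gain, _, drug = -best[0], best[1], best[2]
        if gain <= 0 or gain < cfg.min_gain:
            break
        selected.append(drug)
        remaining.discard(drug)
        covered |= {p for p in in_pool_targets[drug] if p not in covered}
        trajectory.append((drug, gain, len(covered)))
    return SelectionResult(
        selected_drugs=tuple(selected),
        covered=frozenset(covered),
        trajectory=tuple(trajectory),
        protein_scores=dict(scores),
    )


def covered_score(
    subset: Sequence[str],
    scores: Mapping[str, float],
    in_pool_targets: Mapping[str, frozenset[str]],
) -> float:
    union: set[str] = set()
    for drug in subset:
        union |= in_pool_targets[drug]
    return sum(scores[p] for p in union)


def brute_force_coverage(
    scores: Mapping[str, float],
    drug_targets: Mapping[str, frozenset[str] | set[str]],
    k: int,
    cfg: GreedyConfig | None = None,
) -> tuple[tuple[str, ...], float]:
    """Exhaustive optimum over all k-subsets of drugs (oracle; <= 20 drugs).

    Ties break toward the subset with fewer total targets, then
    lexicographically, matching the greedy tie-break.
    """
    cfg = cfg or GreedyConfig()
    drugs = sorted(drug_targets)
    if len(drugs) > 20:
        raise InputError(
            f"{len(drugs)} drugs is too many for exhaustive search; "
            "sample the drug pool down to <= 20 first"
        )
    if not 0 <= k <= len(drugs):
        raise InputError(f"k must lie in [0, {len(drugs)}], got {k}")
    pool = _pool(scores, cfg)
    in_pool_targets = {
        drug: frozenset(t for t in targets if t in pool)
        for drug, targets in drug_targets.items()
    }
    total_sizes = {drug: len(drug_targets[drug]) for drug in drugs}
    best_subset: tuple[str, ...] = ()
    best_key: tuple[float, int, tuple[str, ...]] | None = None
    for subset in itertools.combinations(drugs, k):
        score = covered_score(subset, scores, in_pool_targets)
        key = (-score, sum(total_sizes[d] for d in subset), subset)
        if best_key is None or key < best_key:
            best_key = key
            best_subset = subset
    assert best_key is not None
    return best_subset, -best_key[0]


def write_selection_json(result: SelectionResult, path: str | Path) -> None:
    payload = {
        "selected_drugs": list(result.selected_drugs),
        "covered": sorted(result.covered),
        "trajectory": [
            {"drug": d, "marginal_gain": g, "cumulative_covered": c}
            for d, g, c in result.trajectory
        ],
        "protein_scores": dict(sorted(result.protein_scores.items())),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
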