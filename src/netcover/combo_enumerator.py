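"""Drug-combination enumeration under pairwise interaction-safety constraints.

Given a drug–target map and a symmetric table of known drug–drug
interactions (DDIs), this module enumerates every 2- or 3-drug combination,
flags a combination as safe only when *no* member pair has a reportable
interaction (pairwise closure), and ranks combinations by hub coverage —
the number of distinct network proteins the combined drugs hit.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import InputError

SEVERITY_LEVELS = ("minor", "moderate", "major", "unspecified")


def _pair_key(a: str, b: str) -> tuple[str, str]:
    if a == b:
        raise InputError(f"self-pair {a!r}–{b!r} is not a valid drug pair")
    return (a, b) if a < b else (b, a)


class DDIMatrix:
    """Symmetric pairwise drug–drug interaction status with severity labels.

    Stored as a map from unordered drug pairs to ``(interacting, severity)``;
    symmetry is by construction and self-pairs are rejected. Pairs never
    entered are treated as interaction-free (a warning is emitted the first
    time such a pair is queried through :meth:`interacting`).
    """

    def __init__(self) -> None:
        self._pairs: dict[tuple[str, str], tuple[bool, str]] = {}
        self._warned: set[tuple[str, str]] = set()

    def set_pair(self, a: str, b: str, interacting: bool, severity: str = "unspecified") -> None:
        if severity not in SEVERITY_LEVELS:
            raise InputError(
                f"severity {severity!r} not in {SEVERITY_LEVELS}"
            )
        self._pairs[_pair_key(a, b)] = (bool(interacting), severity)

    def has_pair(self, a: str, b: str) -> bool:
        return _pair_key(a, b) in self._pairs

    def interacting(self, a: str, b: str) -> bool:
        key = _pair_key(a, b)
        if key not in self._pairs:
            if key not in self._warned:
                warnings.warn(
                    f"pair {key[0]}–{key[1]} absent from DDI table; "
                    "treated as interaction-free",
                    stacklevel=2,
                )
                self._warned.add(key)
            return False
        return self._pairs[key][0]

    def severity(self, a: str, b: str) -> str:
        key = _pair_key(a, b)
        if key not in self._pairs:
            return "unspecified"
        return self._pairs[key][1]

    @property
    def pairs(self) -> dict[tuple[str, str], tuple[bool, str]]:
        return dict(self._pairs)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, bool, str]]
    ) -> "DDIMatrix":
        ddi = cls()
        for a, b, interacting, severity in records:
            ddi.set_pair(a, b, interacting, severity)
        return ddi

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DDIMatrix":
        """Build from a 4-column table (drug_a, drug_b, interacting, severity)."""
        required = {"drug_a", "drug_b", "interacting"}
        if not required.issubset(frame.columns):
            raise InputError(f"DDI table must have columns {sorted(required)}")
        ddi = cls()
        for row in frame.itertuples(index=False):
            severity = getattr(row, "severity", "unspecified")
            ddi.set_pair(str(row.drug_a), str(row.drug_b), bool(int(row.interacting)), str(severity))
        return ddi

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"drug_a": a, "drug_b": b, "interacting": int(flag), "severity": sev}
            for (a, b), (flag, sev) in sorted(self._pairs.items())
        ]
        return pd.DataFrame(rows, columns=["drug_a", "drug_b", "interacting", "severity"])


def read_ddi_tsv(path: str | Path) -> DDIMatrix:
    return DDIMatrix.from_frame(pd.read_csv(path, sep="\t", dtype={"drug_a": str, "drug_b": str}))


def write_ddi_tsv(ddi: DDIMatrix, path: str | Path) -> None:
    ddi.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ComboReport:
    """A candidate drug combination with its safety verdict and hub coverage."""

    combo: frozenset[str]
    safe: bool
    coverage: int
    covered_set: frozenset[str]
    culprit_pairs: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    @property
    def sorted_combo(self) -> tuple[str, ...]:
        return tuple(sorted(self.combo))


def coverage(
    combo: Iterable[str], drug_targets: Mapping[str, frozenset[str] | set[str]]
) -> int:
    """Number of distinct proteins hit by the union of the combo's target sets."""
    return len(covered_set(combo, drug_targets))


def covered_set(
    combo: Iterable[str], drug_targets: Mapping[str, frozenset[str] | set[str]]
) -> frozenset[str]:
    out: set[str] = set()
    for drug in combo:
        if drug not in drug_targets:
            raise InputError(f"unknown drug {drug!r}: not present in the drug–target map")
        out |= set(drug_targets[drug])
    return frozenset(out)


def safety_check(
    combo: Iterable[str], ddi: DDIMatrix
) -> tuple[bool, tuple[tuple[str, str], ...]]:
    """A combination is safe iff every unordered member pair is non-interacting.

    Returns the verdict and the list of culprit (interacting) pairs; an empty
    or single-drug combo is vacuously safe.
    """
    drugs = sorted(set(combo))
    culprits = tuple(
        (a, b) for a, b in itertools.combinations(drugs, 2) if ddi.interacting(a, b)
    )
    return (len(culprits) == 0, culprits)


def enumerate_combos(
    drug_ids: Sequence[str],
    drug_targets: Mapping[str, frozenset[str] | set[str]],
    ddi: DDIMatrix,
    k: int,
) -> list[ComboReport]:
    """Enumerate all C(n, k) combinations of ``drug_ids``, ranked for triage.

    Reports are sorted safe-first, then by decreasing coverage, then
    lexicographically, so the head of the list is the best safe regimen.
    """
    if k not in (2, 3):
        raise InputError(f"combination size k must be 2 or 3, got {k}")
    drugs = sorted(set(drug_ids))
    if len(drugs) != len(drug_ids):
        raise InputError("drug_ids contains duplicates")
    missing = [d for d in drugs if d not in drug_targets]
    if missing:
        raise InputError(f"drugs absent from the drug–target map: {missing}")

    reports: list[ComboReport] = []
    for subset in itertools.combinations(drugs, k):
        cov = covered_set(subset, drug_targets)
        safe, culprits = safety_check(subset, ddi)
        reports.append(
            ComboReport(
                combo=frozenset(subset),
                safe=safe,
                coverage=len(cov),
                covered_set=cov,
                culprit_pairs=culprits,
            )
        )
    assert len(reports) == comb(len(drugs), k)
    reports.sort(key=lambda r: (not r.safe, -r.coverage, r.sorted_combo))
    return reports


def reports_to_frame(reports: Sequence[ComboReport]) -> pd.DataFrame:
    rows = [
        {
            "combo": "+".join(r.sorted_combo),
            "safe": int(r.safe),
            "coverage": r.coverage,
            "covered_set": ",".join(sorted(r.covered_set)),
        }
        for r in reports
    ]
    return pd.DataFrame(rows, columns=["combo", "safe", "coverage", "covered_set"])


def write_reports_tsv(reports: Sequence[ComboReport], path: str | Path) -> None:
    reports_to_frame(reports).to_csv(path, sep="\t", index=False)
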