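"""Drug-likeness arithmetic: formula weights, Lipinski rule of five, toxicity flags.

Molecular weight is computed from a Hill-notation formula using an embedded
table of conventional atomic weights, so the screen needs no structure file
and no external service. The rule-of-five check uses Lipinski's original
convention (MW <= 500, HBD <= 5, HBA <= 10, LogP <= 5; at most one
violation passes). Toxicity interpretation applies the standard published
cutoffs: a maximum tolerated dose at or below 0.477 log(mg/kg/day) flags
low tolerance, and a fathead-minnow LC50 strictly below 0.5 mM flags acute
aquatic toxicity.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from .errors import FormulaParseError, InputError

# Conventional atomic weights (g/mol), 2021 IUPAC abridged values.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.95, "K": 39.098, "Ca": 40.078,
    "Ti": 47.867, "V": 50.942, "Cr": 51.996, "Mn": 54.938, "Fe": 55.845,
    "Co": 58.933, "Ni": 58.693, "Cu": 63.546, "Zn": 65.38, "Ga": 69.723,
    "Ge": 72.630, "As": 74.922, "Se": 78.971, "Br": 79.904, "Kr": 83.798,
    "Rb": 85.468, "Sr": 87.62, "Mo": 95.95, "Ru": 101.07, "Rh": 102.91,
    "Pd": 106.42, "Ag": 107.87, "Cd": 112.41, "Sn": 118.71, "Sb": 121.76,
    "Te": 127.60, "I": 126.90, "Cs": 132.91, "Ba": 137.33, "W": 183.84,
    "Pt": 195.08, "Au": 196.97, "Hg": 200.59, "Pb": 207.2, "Bi": 208.98,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

# RO5 thresholds, Lipinski's original four rules.
RO5_RULES: dict[str, float] = {"mw": 500.0, "hbd": 5.0, "hba": 10.0, "logp": 5.0}

MTD_THRESHOLD_LOG_MG_KG_DAY = 0.477
MINNOW_LC50_TOXIC_MM = 0.5


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an element-count formula ("C15H15NO5") into {element: count}.

    No parentheses, isotopes, or charges; repeated element symbols
    accumulate. Errors report the character position of the failure.
    """
    if not isinstance(formula, str) or not formula:
        raise FormulaParseError("empty molecular formula")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(formula):
        match = _TOKEN.match(formula, pos)
        if not match or not match.group(1):
            raise FormulaParseError(
                f"malformed formula {formula!r} at position {pos}: "
                f"unexpected {formula[pos]!r}"
            )
        element, count_str = match.groups()
        if element not in ATOMIC_WEIGHTS:
            raise FormulaParseError(
                f"unknown element {element!r} at position {match.start(1)} in {formula!r}"
            )
        count = int(count_str) if count_str else 1
        if count < 1:
            raise FormulaParseError(
                f"element count must be >= 1 at position {match.start(2)} in {formula!r}"
            )
        counts[element] = counts.get(element, 0) + count
        pos = match.end()
    return counts


def hill_formula(counts: dict[str, int]) -> str:
    """Canonical Hill string: C first, then H, then other elements alphabetically."""
    if not counts:
        raise FormulaParseError("empty element counts")
    ordered: list[str] = []
    if "C" in counts:
        ordered.append("C")
        if "H" in counts:
            ordered.append("H")
        ordered.extend(sorted(e for e in counts if e not in ("C", "H")))
    else:
        ordered.extend(sorted(counts))
    return "".join(
        f"{e}{counts[e]}" if counts[e] > 1 else e for e in ordered
    )


def molecular_weight(formula: str) -> float:
    """Formula weight in g/mol, rounded half-up to 2 decimals.

    Additive under concatenation: mw(A + B) == mw(A) + mw(B) before rounding.
    """
    counts = parse_formula(formula)
    exact = sum(Decimal(repr(ATOMIC_WEIGHTS[e])) * n for e, n in counts.items())
    return float(exact.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MoleculeDescriptors:
    """Physicochemical descriptors of one candidate molecule.

    ``mw`` may be omitted when ``formula`` is given (it is then derived);
    ``psa`` (polar surface area, A^2) and ``rb`` (rotatable bonds) are
    carried for reporting but do not enter the four RO5 rules.
    """

    formula: str = ""
    mw: float | None = None
    psa: float | None = None
    rb: int | None = None
    hba: int | None = None
    hbd: int | None = None
    logp: float | None = None

    def resolved_mw(self) -> float:
        if self.mw is not None:
            return float(self.mw)
        if self.formula:
            return molecular_weight(self.formula)
        raise InputError("missing descriptor 'mw' (and no formula to derive it from)")


@dataclass(frozen=True)
class Ro5Result:
    violations: int
    verdicts: dict[str, bool]  # rule name -> True when the rule is satisfied
    passes: bool


def ro5_check(d: MoleculeDescriptors) -> Ro5Result:
    """Count rule-of-five violations; at most one violation still passes."""
    mw = d.resolved_mw()
    values = {"mw": mw, "hbd": d.hbd, "hba": d.hba, "logp": d.logp}
    for name, value in values.items():
        if value is None:
            raise InputError(f"missing descriptor {name!r}")
    verdicts = {name: float(values[name]) <= RO5_RULES[name] for name in RO5_RULES}
    violations = sum(not ok for ok in verdicts.values())
    return Ro5Result(violations=violations, verdicts=verdicts, passes=violations <= 1)


@dataclass(frozen=True)
class ToxicityInputs:
    max_tolerated_dose: float  # log(mg/kg/day)
    minnow_lc50: float  # mM
    ames_positive: bool = False
    hepatotoxic: bool = False
    skin_irritant: bool = False

    def __post_init__(self) -> None:
        if self.minnow_lc50 <= 0:
            raise InputError(f"minnow_lc50 must be > 0, got {self.minnow_lc50!r}")


@dataclass(frozen=True)
class ToxicityVerdict:
    acutely_toxic_minnow: bool
    low_tolerated_dose: bool
    mutagenic: bool
    hepatotoxic: bool
    skin_irritant: bool

    @property
    def all_clear(self) -> bool:
        return not any(
            (
                self.acutely_toxic_minnow,
                self.low_tolerated_dose,
                self.mutagenic,
                self.hepatotoxic,
                self.skin_irritant,
            )
        )


def toxicity_flags(t: ToxicityInputs) -> ToxicityVerdict:
    """Interpret predicted toxicity values against the standard cutoffs.

    Minnow LC50 strictly below 0.5 mM means acutely toxic; a maximum
    tolerated dose at or below 0.477 log(mg/kg/day) means low tolerance.
    """
    return ToxicityVerdict(
        acutely_toxic_minnow=t.minnow_lc50 < MINNOW_LC50_TOXIC_MM,
        low_tolerated_dose=t.max_tolerated_dose <= MTD_THRESHOLD_LOG_MG_KG_DAY,
        mutagenic=t.ames_positive,
        hepatotoxic=t.hepatotoxic,
        skin_irritant=t.skin_irritant,
    )


def screen_to_json(
    d: MoleculeDescriptors, ro5: Ro5Result, verdict: ToxicityVerdict | None, path: str | Path
) -> None:
    payload = {
        "descriptors": asdict(d) | {"mw": d.resolved_mw()},
        "ro5": {"violations": ro5.violations, "verdicts": ro5.verdicts, "passes": ro5.passes},
    }
    if verdict is not None:
        payload["toxicity"] = asdict(verdict) | {"all_clear": verdict.all_clear}
    Path(path).write_text(json.dumps(payload, indent=2))
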