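"""Elemental-formula arithmetic for small-molecule mass spectrometry.

Everything downstream — metabolite prediction, accurate-mass screening,
fragment annotation — reduces to sums and differences of monoisotopic
atomic masses.  This module owns that arithmetic: formula parsing and
formatting, neutral and ionic monoisotopic masses, ppm errors, ring-plus-
double-bond equivalents (RDB), mass defects, and molecular-formula
decomposition of an accurate ion m/z under element-count and RDB
constraints.

Two single-charge ion conventions are supported.  The *physical*
convention adds or removes a proton (1.00728 Da) for [M+H]+ / [M-H]-.
Some published tables instead tabulate negative-mode theoreticals as
M - H(atom) - electron; the *paper_negative* convention reproduces those
values.  The physical convention is the default everywhere.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

from .constants import ELECTRON_MASS, H_ATOM_MASS, MASS_TABLE, PROTON_MASS

__all__ = [
    "ChemicalFormula",
    "FormulaError",
    "IonMode",
    "IonConvention",
    "IonSpecies",
    "DecompositionConstraints",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "neutral_mass_from_mz",
    "ppm_error",
    "rdb",
    "mass_defect",
    "nominal_mz",
    "decompose_mass",
]


class FormulaError(ValueError):
    """Raised for malformed or chemically invalid formula input."""


# Hill-style token: capital letter, optional lowercase, optional count.
_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ChemicalFormula:
    """An elemental composition: an element -> count map.

    Counts are non-negative integers, at least one nonzero, and every
    symbol must be present in the configured mass table.  Instances are
    immutable and hashable so they can key graph nodes and dict caches.
    """

    counts: tuple[tuple[str, int], ...]

    def __init__(self, counts: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = dict(counts)
        for el, n in items.items():
            if el not in MASS_TABLE:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"negative or non-integer count for {el}: {n!r}")
        items = {el: n for el, n in items.items() if n > 0}
        if not items:
            raise FormulaError("formula must contain at least one atom")
        object.__setattr__(self, "counts", tuple(sorted(items.items())))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        merged = self.as_dict()
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) + n
        return ChemicalFormula(merged)

    def __sub__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        merged = self.as_dict()
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise FormulaError(
                    f"subtraction yields negative {el} count"
                )
        return ChemicalFormula(merged)

    def hill(self) -> str:
        """Hill-order formula string (C first, H second, rest alphabetic)."""
        d = self.as_dict()
        parts: list[str] = []
        for el in ["C", "H"] + sorted(k for k in d if k not in ("C", "H")):
            n = d.get(el, 0)
            if n == 0:
                continue
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> ChemicalFormula:
    """Parse a Hill-style formula string into a :class:`ChemicalFormula`.

    Accepts plain strings ("C19H18O7") and the fixture-table dialect in
    which counts are fenced by underscores and stray spaces may appear
    ("C_19_H_18_O_7_", "C_20_ H_21_O_8_"); underscores and whitespace are
    stripped before tokenising.
    """
    cleaned = text.replace("_", "").replace(" ", "").strip()
    if not cleaned:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(cleaned):
        m = _TOKEN.match(cleaned, pos)
        if m is None or m.end() == pos:
            raise FormulaError(
                f"malformed formula {text!r}: unparseable at {cleaned[pos:]!r}"
            )
        el, digits = m.groups()
        if el not in MASS_TABLE:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ChemicalFormula(counts)


class IonMode(str, Enum):
    protonated_pos = "protonated_pos"
    deprotonated_neg = "deprotonated_neg"


class IonConvention(str, Enum):
    physical = "physical"
    paper_negative = "paper_negative"


@dataclass(frozen=True)
class IonSpecies:
    """A singly charged ±H ion of a neutral molecule."""

    formula: ChemicalFormula
    mode: IonMode
    convention: IonConvention = IonConvention.physical


def monoisotopic_mass(f: ChemicalFormula) -> float:
    """Neutral monoisotopic mass in Da: sum of count x atomic mass."""
    return sum(n * MASS_TABLE[el] for el, n in f.counts)


def ion_mz(
    formula: ChemicalFormula,
    mode: IonMode = IonMode.protonated_pos,
    convention: IonConvention = IonConvention.physical,
) -> float:
    """m/z of the singly charged ±H ion of a neutral formula.

    physical: [M+H]+ = M + m_p; [M-H]- = M - m_p.
    paper_negative: [M-H]- = M - m_H - m_e (tabulation convention found in
    some published theoretical-mass columns); positive mode is unaffected.
    """
    m = monoisotopic_mass(formula)
    mode = IonMode(mode)
    if mode is IonMode.protonated_pos:
        return m + PROTON_MASS
    if IonConvention(convention) is IonConvention.paper_negative:
        return m - H_ATOM_MASS - ELECTRON_MASS
    return m - PROTON_MASS


def neutral_mass_from_mz(
    mz: float,
    mode: IonMode,
    convention: IonConvention = IonConvention.physical,
) -> float:
    """Invert :func:`ion_mz`: neutral monoisotopic mass from an ion m/z."""
    mode = IonMode(mode)
    if mode is IonMode.protonated_pos:
        return mz - PROTON_MASS
    if IonConvention(convention) is IonConvention.paper_negative:
        return mz + H_ATOM_MASS + ELECTRON_MASS
    return mz + PROTON_MASS


def cation_mz(f: ChemicalFormula) -> float:
    """m/z of a formula read as an even-electron cation (minus one electron)."""
    return monoisotopic_mass(f) - ELECTRON_MASS


def ppm_error(experimental: float, theoretical: float) -> float:
    """(experimental - theoretical) / theoretical x 1e6."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (experimental - theoretical) / theoretical * 1e6


def rdb(f: ChemicalFormula) -> float:
    """Ring-plus-double-bond equivalents: C - H/2 + N/2 + 1.

    O and S contribute zero.  Computed on neutral formulas; ion formulas
    give half-integers, which is why decomposition evaluates RDB on the
    neutral composition.
    """
    return f["C"] - f["H"] / 2 + f["N"] / 2 + 1


def mass_defect(mass: float) -> float:
    """Mass defect in mDa: (mass - nearest integer) x 1000."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    return (mass - round(mass)) * 1000.0


def nominal_mz(
    formula: ChemicalFormula,
    mode: IonMode = IonMode.protonated_pos,
    convention: IonConvention = IonConvention.physical,
) -> int:
    """Ion m/z rounded to the nearest integer (ion-trap nominal mass)."""
    return round(ion_mz(formula, mode, convention))


def nominal_cation_mz(f: ChemicalFormula) -> int:
    """Nominal m/z of a fragment formula read directly as a cation."""
    return round(cation_mz(f))


@dataclass(frozen=True)
class DecompositionConstraints:
    """Element-count ranges, RDB range and ppm tolerance for decomposition.

    Defaults: C 0-30, H 0-50, O 0-20, S 0-2, N 0-3, RDB 0-15, 5 ppm.
    """

    element_ranges: tuple[tuple[str, int, int], ...] = (
        ("C", 0, 30),
        ("H", 0, 50),
        ("O", 0, 20),
        ("S", 0, 2),
        ("N", 0, 3),
    )
    rdb_range: tuple[float, float] = (0.0, 15.0)
    tolerance_ppm: float = 5.0

    def __post_init__(self) -> None:
        for el, lo, hi in self.element_ranges:
            if el not in MASS_TABLE:
                raise FormulaError(f"unknown element in constraints: {el}")
            if lo > hi or lo < 0:
                raise ValueError(f"empty count range for {el}: [{lo}, {hi}]")
        if self.rdb_range[0] > self.rdb_range[1]:
            raise ValueError("empty RDB range")
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance must be positive")


def _heteroatom_count(f: ChemicalFormula) -> int:
    return sum(n for el, n in f.counts if el not in ("C", "H"))


def decompose_mass(
    target_mz: float,
    mode: IonMode,
    constraints: DecompositionConstraints = DecompositionConstraints(),
    convention: IonConvention = IonConvention.physical,
) -> list[ChemicalFormula]:
    """All neutral formulas whose ±H ion matches an accurate m/z.

    Enumerates element counts over the constraint ranges with
    branch-and-bound pruning on the residual mass, keeps candidates whose
    ion m/z lies within ``tolerance_ppm`` of ``target_mz`` and whose
    neutral RDB lies inside the RDB range, and orders the survivors by
    |ppm| ascending, then fewer heteroatoms, then Hill string.

    An empty list is a valid result (no formula fits), not an error.
    """
    neutral_target = neutral_mass_from_mz(target_mz, mode, convention)
    # The acceptance predicate is ppm relative to each candidate's
    # theoretical m/z; the search window is widened marginally so no
    # boundary candidate is pruned before that exact test.
    tol_da = abs(target_mz) * constraints.tolerance_ppm * 1e-6 * (1 + 1e-4) + 1e-9
    if neutral_target + tol_da <= 0:
        return []

    # Put H last so the innermost level can be solved directly.
    ranges = [r for r in constraints.element_ranges if r[0] != "H"]
    h_range = next(
        ((lo, hi) for el, lo, hi in constraints.element_ranges if el == "H"),
        (0, 0),
    )
    elements = [el for el, _, _ in ranges]
    masses = [MASS_TABLE[el] for el in elements]
    h_mass = MASS_TABLE["H"]

    results: list[ChemicalFormula] = []
    counts = [0] * len(elements)

    def recurse(i: int, remaining: float) -> None:
        if remaining < -tol_da:
            return
        if i == len(elements):
            # Solve for the H count closest to the residual mass.
            h_center = remaining / h_mass
            for h in {math.floor(h_center), math.ceil(h_center)}:
                if h < h_range[0] or h > h_range[1]:
                    continue
                resid = remaining - h * h_mass
                if abs(resid) > tol_da:
                    continue
                d = {el: c for el, c in zip(elements, counts) if c > 0}
                if h > 0:
                    d["H"] = h
                if not d:
                    continue
                cand = ChemicalFormula(d)
                if not (
                    constraints.rdb_range[0] <= rdb(cand) <= constraints.rdb_range[1]
                ):
                    continue
                if cand not in results:
                    results.append(cand)
            return
        lo, hi = ranges[i][1], ranges[i][2]
        m = masses[i]
        # Residual-mass bound: cannot exceed remaining + tolerance.
        hi = min(hi, int((remaining + tol_da) // m) if m > 0 else hi)
        for c in range(lo, hi + 1):
            counts[i] = c
            recurse(i + 1, remaining - c * m)
        counts[i] = 0

    recurse(0, neutral_target)

    def sort_key(f: ChemicalFormula):
        theo = ion_mz(f, mode, convention)
        return (abs(ppm_error(target_mz, theo)), _heteroatom_count(f), f.hill())

    results.sort(key=sort_key)
    # Soundness: drop anything outside tolerance when measured in ppm terms.
    return [
        f
        for f in results
        if abs(ppm_error(target_mz, ion_mz(f, mode, convention)))
        <= constraints.tolerance_ppm
    ]
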