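"""MS^n confirmation: neutral losses, diagnostic ions, skeleton classes.

Collision-induced dissociation of polymethoxylated flavonoids follows a
small set of reproducible patterns.  Methoxylated cores shed methyl
radicals, so product ions sit n x 15 below their precursor; phase-II
conjugates open with the loss of the intact conjugate (80 Da for SO3,
176 Da for the glucuronyl moiety); and retro-Diels-Alder cleavage of the
C-ring yields skeleton-diagnostic product ions (DPIs): the 151+X series
for flavones (X being the substituent mass: 0, 14, 16, 30 by default),
m/z 211 as an MS^2 base peak for flavanones, and m/z 221 with a minor
197 for chalcones.

This module turns those patterns into rule tables and a classifier over
precursor-linked MS^n trees, then scores screened candidates into
identified/potential records.  All fragment matching is nominal-mass
(ion trap) with a ±0.5 Th default tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .formula import (
    ChemicalFormula,
    monoisotopic_mass,
    nominal_cation_mz,
    parse_formula,
)
from .spectra import MSnTree, SpectrumRecord
from .screening import ScreenHit

__all__ = [
    "NeutralLossRule",
    "DPIRule",
    "SkeletonClass",
    "LossAnnotation",
    "DPIMatch",
    "EvidenceBundle",
    "default_loss_rules",
    "default_dpi_rules",
    "detect_neutral_losses",
    "screen_methyl_losses",
    "methyl_ladder_depth",
    "match_dpis",
    "classify_skeleton",
    "confirm_candidate",
    "ConfirmationResult",
]

NOMINAL_TOLERANCE = 0.5  # Th; ion-trap fragment masses are nominal


@dataclass(frozen=True)
class NeutralLossRule:
    """A named neutral loss: formula, exact mass and nominal mass."""

    name: str
    formula: ChemicalFormula
    conjugate: bool = False  # True for phase-II conjugate losses

    @property
    def exact_mass(self) -> float:
        return monoisotopic_mass(self.formula)

    @property
    def nominal(self) -> int:
        return round(self.exact_mass)


def default_loss_rules() -> list[NeutralLossRule]:
    return [
        NeutralLossRule("CH3 radical", parse_formula("CH3")),
        NeutralLossRule("methane", parse_formula("CH4")),
        NeutralLossRule("water", parse_formula("H2O")),
        NeutralLossRule("CO", parse_formula("CO")),
        NeutralLossRule("OCH3 radical", parse_formula("CH3O")),
        NeutralLossRule("SO3", parse_formula("SO3"), conjugate=True),
        NeutralLossRule("glucuronyl", parse_formula("C6H8O6"), conjugate=True),
    ]


@dataclass(frozen=True)
class DPIRule:
    """Diagnostic product ions of one skeleton class.

    ``fragment_formulas`` are even-electron cation formulas; their
    nominal m/z must equal ``nominal_mzs`` entry-wise (self-consistency
    is asserted in tests).  ``offsets`` extends the first fragment into
    a +X substituent series (the flavone 151+X rule).
    """

    skeleton: "SkeletonClass"
    fragment_formulas: tuple[ChemicalFormula, ...]
    nominal_mzs: tuple[int, ...]
    offsets: tuple[int, ...] = (0,)
    base_peak_required: bool = False

    def accepted_nominals(self) -> dict[int, int]:
        """nominal m/z -> X offset, over the rule's whole series."""
        out: dict[int, int] = {}
        for x in self.offsets:
            out[self.nominal_mzs[0] + x] = x
        for nm in self.nominal_mzs[1:]:
            out.setdefault(nm, 0)
        return out


class SkeletonClass(str, Enum):
    polymethoxyflavone = "polymethoxyflavone"
    polymethoxyflavanone = "polymethoxyflavanone"
    polymethoxychalcone = "polymethoxychalcone"
    sulfate_conjugate = "sulfate_conjugate"
    glucuronide_conjugate = "glucuronide_conjugate"
    unclassified = "unclassified"


def default_dpi_rules() -> list[DPIRule]:
    return [
        DPIRule(
            skeleton=SkeletonClass.polymethoxyflavone,
            fragment_formulas=(parse_formula("C8H7O3"),),
            nominal_mzs=(151,),
            offsets=(0, 14, 16, 30),
        ),
        DPIRule(
            skeleton=SkeletonClass.polymethoxyflavanone,
            fragment_formulas=(parse_formula("C10H11O5"),),
            nominal_mzs=(211,),
            base_peak_required=True,
        ),
        DPIRule(
            skeleton=SkeletonClass.polymethoxychalcone,
            fragment_formulas=(parse_formula("C12H13O4"), parse_formula("C9H9O5")),
            nominal_mzs=(221, 197),
        ),
    ]


@dataclass(frozen=True)
class LossAnnotation:
    rule_name: str
    ms_level: int
    parent_mz: float
    fragment_mz: float
    from_precursor: bool


@dataclass(frozen=True)
class DPIMatch:
    skeleton: SkeletonClass
    nominal_mz: int
    observed_mz: float
    intensity: float
    ms_level: int
    offset_x: int
    is_base_peak: bool


@dataclass
class EvidenceBundle:
    """Everything the classifier saw in one spectral tree."""

    losses: list[LossAnnotation] = field(default_factory=list)
    dpis: list[DPIMatch] = field(default_factory=list)
    methyl_ladder: int = 0
    conjugate_loss: str | None = None
    inner_skeleton: SkeletonClass | None = None
    conflict: bool = False

    def has_any(self) -> bool:
        return bool(self.losses or self.dpis or self.methyl_ladder)


def detect_neutral_losses(
    tree: MSnTree,
    rules: list[NeutralLossRule] | None = None,
    tolerance: float = NOMINAL_TOLERANCE,
) -> list[LossAnnotation]:
    """Annotate precursor -> product mass differences matching a rule.

    Every spectrum of the tree is scanned: the difference between its
    precursor and each product peak is compared against each rule's
    exact and nominal loss mass within ``tolerance`` Th.  Output order
    follows (ms level, fragment m/z descending), so it is invariant to
    the input peak-list permutation and to intensity scaling.
    """
    if rules is None:
        rules = default_loss_rules()
    annotations: list[LossAnnotation] = []
    for spec in tree.all_spectra():
        if spec.precursor_mz is None:
            continue
        for peak in spec.peaks:
            diff = spec.precursor_mz - peak.mz
            if diff <= 0:
                continue
            for rule in rules:
                if (
                    abs(diff - rule.exact_mass) <= tolerance
                    or abs(diff - rule.nominal) <= tolerance
                ):
                    annotations.append(
                        LossAnnotation(
                            rule_name=rule.name,
                            ms_level=spec.ms_level,
                            parent_mz=spec.precursor_mz,
                            fragment_mz=peak.mz,
                            from_precursor=True,
                        )
                    )
    annotations.sort(key=lambda a: (a.ms_level, -a.fragment_mz, a.rule_name))
    return annotations


def screen_methyl_losses(
    spectrum: SpectrumRecord, tolerance: float = NOMINAL_TOLERANCE
) -> bool:
    """True iff some product ion sits n x 15 (n >= 1) below the precursor.

    The inclusion screen used to pull methoxylated candidates out of
    large MS^2 datasets: successive methyl-radical losses leave peaks at
    precursor - 15, -30, -45, ... on the nominal mass scale.
    """
    if spectrum.ms_level < 2 or spectrum.precursor_mz is None:
        raise ValueError("methyl-loss screening needs an MS^n spectrum")
    for peak in spectrum.peaks:
        diff = spectrum.precursor_mz - peak.mz
        if diff < 15 - tolerance:
            continue
        n = round(diff / 15)
        if n >= 1 and abs(diff - 15 * n) <= tolerance:
            return True
    return False


def methyl_ladder_depth(
    tree: MSnTree, tolerance: float = NOMINAL_TOLERANCE
) -> int:
    """Depth of the consecutive CH3-loss ladder under the root precursor.

    The largest n such that peaks exist anywhere in the tree at
    root_precursor - 15 k for every k = 1..n.  MS^3 re-isolation of the
    first loss product extends the ladder (e.g. MS2 shows -15, MS3 of
    that ion shows -30).
    """
    prec = tree.precursor_mz
    mzs = [p.mz for _, p in tree.all_peaks()]
    depth = 0
    k = 1
    while True:
        target = prec - 15 * k
        if target <= 0 or not any(abs(mz - target) <= tolerance for mz in mzs):
            break
        depth = k
        k += 1
    return depth


def match_dpis(
    tree: MSnTree,
    rules: list[DPIRule] | None = None,
    tolerance: float = NOMINAL_TOLERANCE,
) -> list[DPIMatch]:
    """Find every diagnostic product ion anywhere in the tree."""
    if rules is None:
        rules = default_dpi_rules()
    matches: list[DPIMatch] = []
    for spec in tree.all_spectra():
        base = spec.base_peak()
        for rule in rules:
            for nominal, x in sorted(rule.accepted_nominals().items()):
                for peak in spec.peaks:
                    if abs(peak.mz - nominal) <= tolerance:
                        matches.append(
                            DPIMatch(
                                skeleton=rule.skeleton,
                                nominal_mz=nominal,
                                observed_mz=peak.mz,
                                intensity=peak.intensity,
                                ms_level=spec.ms_level,
                                offset_x=x,
                                is_base_peak=base is not None and peak is base,
                            )
                        )
    matches.sort(key=lambda m: (m.ms_level, m.nominal_mz, m.observed_mz))
    return matches


def _conjugate_loss(
    tree: MSnTree, tolerance: float
) -> tuple[str | None, MSnTree | None]:
    """Check the root spectrum for a 176/80 Da conjugate loss.

    Returns (rule name, aglycone sub-tree) where the sub-tree is the
    child spectrum that re-isolated the aglycone ion, if acquired.
    """
    prec = tree.precursor_mz
    for rule in default_loss_rules():
        if not rule.conjugate:
            continue
        for peak in tree.spectrum.peaks:
            diff = prec - peak.mz
            if (
                abs(diff - rule.exact_mass) <= tolerance
                or abs(diff - rule.nominal) <= tolerance
            ):
                sub = next(
                    (
                        c
                        for c in tree.children
                        if abs(c.precursor_mz - peak.mz) <= tolerance
                    ),
                    None,
                )
                return rule.name, sub
    return None, None


def classify_skeleton(
    tree: MSnTree,
    tolerance: float = NOMINAL_TOLERANCE,
) -> tuple[SkeletonClass, EvidenceBundle]:
    """Assign a core-skeleton class to one MS^n tree.

    Decision order (first match wins): glucuronyl loss (176 Da) from the
    precursor; SO3 loss (80 Da); m/z 211 as the MS^2 base peak
    (flavanone); DPI 221 present (chalcone); a 151+X DPI or a methyl
    ladder of depth >= 2 (flavone); otherwise unclassified.  Conjugate
    losses outrank skeleton DPIs because an intact-conjugate loss is
    unambiguous while DPIs can co-occur.  For conjugates the aglycone
    sub-tree, when acquired, is classified recursively and recorded as
    ``inner_skeleton``.

    The depth >= 2 ladder requirement for flavones avoids promoting a
    single methyl loss — common to nearly every methoxylated skeleton —
    into a class call.
    """
    evidence = EvidenceBundle(
        losses=detect_neutral_losses(tree, tolerance=tolerance),
        dpis=match_dpis(tree, tolerance=tolerance),
        methyl_ladder=methyl_ladder_depth(tree, tolerance),
    )

    conj, aglycone = _conjugate_loss(tree, tolerance)
    if conj is not None:
        evidence.conjugate_loss = conj
        if aglycone is not None:
            inner, _ = classify_skeleton(aglycone, tolerance)
            evidence.inner_skeleton = inner
        cls = (
            SkeletonClass.glucuronide_conjugate
            if conj == "glucuronyl"
            else SkeletonClass.sulfate_conjugate
        )
        return cls, evidence

    for m in evidence.dpis:
        if (
            m.skeleton is SkeletonClass.polymethoxyflavanone
            and m.ms_level == 2
            and m.is_base_peak
        ):
            return SkeletonClass.polymethoxyflavanone, evidence
    for m in evidence.dpis:
        if m.skeleton is SkeletonClass.polymethoxychalcone and m.nominal_mz == 221:
            return SkeletonClass.polymethoxychalcone, evidence
    if (
        any(m.skeleton is SkeletonClass.polymethoxyflavone for m in evidence.dpis)
        or evidence.methyl_ladder >= 2
    ):
        return SkeletonClass.polymethoxyflavone, evidence
    return SkeletonClass.unclassified, evidence


@dataclass
class ConfirmationResult:
    """Outcome of matching a screen hit against its MS^n evidence."""

    hit: ScreenHit
    status: str  # "identified" | "potential"
    skeleton: SkeletonClass
    evidence: EvidenceBundle | None
    conflict: bool = False


def expected_skeleton(
    skeleton_tag: str, reaction_path: tuple[str, ...]
) -> SkeletonClass:
    """Map a predicted node (tag + path) to the skeleton class its MS^n
    tree should exhibit.  Conjugation templates dominate: the intact
    conjugate loss is the first fragmentation event."""
    if "glucuronidation" in reaction_path:
        return SkeletonClass.glucuronide_conjugate
    if "sulfation" in reaction_path:
        return SkeletonClass.sulfate_conjugate
    return {
        "flavone": SkeletonClass.polymethoxyflavone,
        "flavanone": SkeletonClass.polymethoxyflavanone,
        "chalcone": SkeletonClass.polymethoxychalcone,
    }.get(skeleton_tag, SkeletonClass.unclassified)


def confirm_candidate(
    hit: ScreenHit,
    trees: list[MSnTree],
    skeleton_tag: str,
    reaction_path: tuple[str, ...],
    tolerance: float = NOMINAL_TOLERANCE,
) -> ConfirmationResult:
    """Score a screen hit against the MS^n trees acquired for its m/z.

    ``identified`` requires at least one tree whose classification
    agrees with the candidate's predicted class.  No tree at all leaves
    the hit ``potential`` (an MS^1-only observation).  Trees whose
    evidence contradicts the prediction — a different class, or no
    matching fragments — leave the hit potential with a conflict flag.
    """
    if not trees:
        return ConfirmationResult(
            hit=hit,
            status="potential",
            skeleton=SkeletonClass.unclassified,
            evidence=None,
        )
    expected = expected_skeleton(skeleton_tag, reaction_path)
    best: tuple[SkeletonClass, EvidenceBundle] | None = None
    for tree in trees:
        cls, evidence = classify_skeleton(tree, tolerance)
        if cls is expected and evidence.has_any():
            return ConfirmationResult(
                hit=hit, status="identified", skeleton=cls, evidence=evidence
            )
        if best is None:
            best = (cls, evidence)
    cls, evidence = best
    evidence.conflict = True
    return ConfirmationResult(
        hit=hit,
        status="potential",
        skeleton=cls,
        evidence=evidence,
        conflict=True,
    )
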