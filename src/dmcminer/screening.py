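"""MS^1 candidate screening: ion chromatograms and mass-defect filters.

Candidate metabolites predicted by the cluster expansion are located in
full-scan data in two complementary ways.  A high-resolution extracted
ion chromatogram (HREIC) sums, per MS^1 scan, the intensity of peaks
within a ppm window around a predicted ion m/z; apexes above a
polarity-specific intensity threshold become screen hits.  Multiple
mass-defect filtering (MMDF) retains only peaks whose fractional mass
falls within ±50 mDa of one of several template defects over a ±50 Da
mass window around the template mass — the templates being the
prototype drug, its glucuronide and its sulfate, whose defects are
derived from their neutral monoisotopic masses.

The printed defect of a published prototype template may not be
derivable from its formula; ``center_defect`` therefore accepts a
manual override so historical filter settings can be replayed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .biotransform import DMCGraph, MetaboliteNode
from .formula import (
    ChemicalFormula,
    IonConvention,
    IonMode,
    ion_mz,
    mass_defect,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
)
from .spectra import Peak, Polarity, SpectrumRecord

__all__ = [
    "MDFTemplate",
    "ChromTrace",
    "ScreenHit",
    "DEFAULT_INTENSITY_THRESHOLDS",
    "hreic",
    "detect_trace_peaks",
    "build_mdf_templates",
    "mmdf",
    "build_parent_ion_list",
    "screen_graph",
]

#: Minimum apex intensity per polarity for a feature to count.
DEFAULT_INTENSITY_THRESHOLDS: dict[Polarity, float] = {
    Polarity.neg: 10_000.0,
    Polarity.pos: 40_000.0,
}


@dataclass(frozen=True)
class MDFTemplate:
    """A (center mass, center defect) pair with window half-widths."""

    name: str
    center_mass: float
    center_defect: float  # mDa
    defect_halfwidth: float = 50.0  # mDa
    mass_halfwidth: float = 50.0  # Da

    def __post_init__(self) -> None:
        if self.defect_halfwidth <= 0 or self.mass_halfwidth <= 0:
            raise ValueError("window half-widths must be positive")

    def accepts(self, mz: float) -> bool:
        return (
            abs(mz - self.center_mass) <= self.mass_halfwidth
            and abs(mass_defect(mz) - self.center_defect) <= self.defect_halfwidth
        )


@dataclass
class ChromTrace:
    """An extracted ion chromatogram: (rt, summed intensity) series."""

    target_mz: float
    tolerance_ppm: float
    points: list[tuple[float, float]]
    empty_run: bool = False  # True when the run had no matching MS^1 scans

    def __post_init__(self) -> None:
        rts = [rt for rt, _ in self.points]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("retention times must be strictly increasing")
        if any(i < 0 for _, i in self.points):
            raise ValueError("intensities must be non-negative")

    def total_intensity(self) -> float:
        return sum(i for _, i in self.points)


@dataclass
class ScreenHit:
    """A candidate node located in MS^1 data."""

    node_key: tuple[ChemicalFormula, str]
    predicted_mz: float
    observed_mz: float
    rt_apex: float
    apex_intensity: float
    polarity: Polarity
    passed_filters: frozenset[str] = frozenset()


def hreic(
    run: Sequence[SpectrumRecord],
    target_mz: float,
    tolerance_ppm: float = 5.0,
    polarity: Polarity | None = None,
) -> ChromTrace:
    """Extract the per-MS^1-scan summed intensity around ``target_mz``.

    Scans with no matching peak contribute zero.  A run with no MS^1
    scans of the requested polarity yields an empty trace flagged
    ``empty_run`` rather than an error.
    """
    tol = target_mz * tolerance_ppm * 1e-6
    points: list[tuple[float, float]] = []
    for spec in run:
        if spec.ms_level != 1:
            continue
        if polarity is not None and spec.polarity is not polarity:
            continue
        total = sum(
            p.intensity for p in spec.peaks if abs(p.mz - target_mz) <= tol
        )
        points.append((spec.retention_time, total))
    return ChromTrace(
        target_mz=target_mz,
        tolerance_ppm=tolerance_ppm,
        points=points,
        empty_run=not points,
    )


def detect_trace_peaks(
    trace: ChromTrace,
    polarity: Polarity,
    thresholds: dict[Polarity, float] = DEFAULT_INTENSITY_THRESHOLDS,
) -> list[tuple[float, float]]:
    """Local maxima of a trace above the polarity intensity threshold.

    A point is an apex when it is at least as intense as both 3-point
    neighbours (run boundaries count as one-sided); plateau ties resolve
    to the earliest point.  No smoothing is applied.
    """
    threshold = thresholds[polarity]
    pts = trace.points
    apexes: list[tuple[float, float]] = []
    for i, (rt, inten) in enumerate(pts):
        if inten < threshold or inten <= 0:
            continue
        left = pts[i - 1][1] if i > 0 else -1.0
        right = pts[i + 1][1] if i + 1 < len(pts) else -1.0
        if inten > left and inten >= right:
            apexes.append((rt, inten))
    return apexes


def build_mdf_templates(
    seed: ChemicalFormula,
    defect_halfwidth: float = 50.0,
    mass_halfwidth: float = 50.0,
    overrides: dict[str, float] | None = None,
) -> list[MDFTemplate]:
    """The three standard filter templates for a prototype drug.

    Centered on the neutral monoisotopic masses of the prototype, its
    glucuronide (+C6H8O6) and its sulfate (+SO3); defects are derived
    from those masses unless ``overrides`` maps a template name to a
    replacement defect in mDa.
    """
    overrides = overrides or {}
    gluc = seed + parse_formula("C6H8O6")
    sulf = seed + parse_formula("SO3")
    out = []
    for name, formula in (
        ("prototype", seed),
        ("glucuronide", gluc),
        ("sulfate", sulf),
    ):
        mass = monoisotopic_mass(formula)
        defect = overrides.get(name, mass_defect(mass))
        out.append(
            MDFTemplate(
                name=name,
                center_mass=mass,
                center_defect=defect,
                defect_halfwidth=defect_halfwidth,
                mass_halfwidth=mass_halfwidth,
            )
        )
    return out


def mmdf(
    peaks: Iterable[tuple[float, float]] | Iterable[Peak],
    templates: Sequence[MDFTemplate],
) -> list[tuple[float, float, frozenset[str]]]:
    """Filter centroid peaks through the mass-defect template windows.

    Returns (mz, intensity, matched template names) for every peak
    accepted by at least one template.
    """
    out: list[tuple[float, float, frozenset[str]]] = []
    for peak in peaks:
        if isinstance(peak, Peak):
            mz, inten = peak.mz, peak.intensity
        else:
            mz, inten = peak
        matched = frozenset(t.name for t in templates if t.accepts(mz))
        if matched:
            out.append((mz, inten, matched))
    return out


def build_parent_ion_list(
    graph: DMCGraph,
    mode: IonMode,
    convention: IonConvention = IonConvention.physical,
) -> list[float]:
    """Sorted, deduplicated predicted ion m/z values for the graph.

    One entry per node formula in the requested polarity; isomeric nodes
    (same formula, different skeleton tag) collapse to one entry.
    Deduplication is at 5 decimal places, the reporting precision.
    """
    seen: set[float] = set()
    for node in graph.nodes():
        mz = round(ion_mz(node.formula, mode, convention), 5)
        seen.add(mz)
    return sorted(seen)


def screen_graph(
    run: Sequence[SpectrumRecord],
    graph: DMCGraph,
    polarity: Polarity,
    tolerance_ppm: float = 5.0,
    thresholds: dict[Polarity, float] = DEFAULT_INTENSITY_THRESHOLDS,
    templates: Sequence[MDFTemplate] | None = None,
    convention: IonConvention = IonConvention.physical,
) -> list[ScreenHit]:
    """HREIC + threshold + MMDF screening of every graph node in a run.

    For each node, the predicted ion m/z is traced through the MS^1
    scans; every apex above the polarity threshold whose nearest actual
    MS^1 peak also passes the mass-defect filter (when templates are
    given) yields one :class:`ScreenHit`.  Multiple apexes on one trace
    become multiple hits (isomers separated by chromatography).
    """
    mode = (
        IonMode.protonated_pos if polarity is Polarity.pos else IonMode.deprotonated_neg
    )
    ms1 = [s for s in run if s.ms_level == 1 and s.polarity is polarity]
    hits: list[ScreenHit] = []
    for node in sorted(
        graph.nodes(), key=lambda n: (n.generation, n.formula.hill(), n.skeleton_tag)
    ):
        predicted = ion_mz(node.formula, mode, convention)
        trace = hreic(run, predicted, tolerance_ppm, polarity)
        if trace.empty_run:
            continue
        for rt_apex, apex_int in detect_trace_peaks(trace, polarity, thresholds):
            # locate the actual centroid peak at the apex scan
            scan = min(ms1, key=lambda s: abs(s.retention_time - rt_apex))
            tol = predicted * tolerance_ppm * 1e-6
            cands = [p for p in scan.peaks if abs(p.mz - predicted) <= tol]
            if not cands:
                continue
            best = max(cands, key=lambda p: p.intensity)
            passed: frozenset[str] = frozenset()
            if templates is not None:
                passed = frozenset(t.name for t in templates if t.accepts(best.mz))
                if not passed:
                    continue
            hits.append(
                ScreenHit(
                    node_key=node.key,
                    predicted_mz=predicted,
                    observed_mz=best.mz,
                    rt_apex=rt_apex,
                    apex_intensity=apex_int,
                    polarity=polarity,
                    passed_filters=passed,
                )
            )
    return hits
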