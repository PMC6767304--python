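"""Pipeline orchestration and report generation.

One round of the iterative workflow: expand the metabolite network one
hop from the current cluster centers, predict ion m/z values, screen
them against the MS^1 data (extracted-ion chromatogram apexes above the
polarity intensity threshold, then mass-defect filtering with windows
derived from every current center), confirm screen hits against their
MS^n trees, and promote confirmed nodes to centers.  Rounds repeat
until a round confirms nothing new or the generation cap is reached.

Candidates seen in MS^1 but lacking (or contradicting) MS^n evidence
are reported as *potential*; confirmed candidates as *identified*.  A
metabolite observed in both polarities collapses into one record with
two ion entries; isomers — same formula and skeleton at different
retention times — become separate records suffixed a/b/c by ascending
retention time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

from .biotransform import (
    DMCGraph,
    MetaboliteNode,
    NodeStatus,
    ReactionTemplate,
    default_templates,
    expand,
    generation_summary,
    promote_centers,
)
from .formula import (
    ChemicalFormula,
    IonConvention,
    IonMode,
    ion_mz,
    ppm_error,
)
from .msn import (
    ConfirmationResult,
    EvidenceBundle,
    SkeletonClass,
    confirm_candidate,
    NOMINAL_TOLERANCE,
)
from .screening import (
    DEFAULT_INTENSITY_THRESHOLDS,
    MDFTemplate,
    ScreenHit,
    build_mdf_templates,
    screen_graph,
)
from .spectra import MSnTree, Polarity, SpectrumRecord, build_msn_trees

__all__ = [
    "ModeObservation",
    "IdentificationRecord",
    "PipelineConfig",
    "run_pipeline",
    "summarize",
    "write_report",
    "read_records_tsv",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (table-style reporting of m/z and ppm)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ModeObservation:
    """Per-polarity ion observation of one metabolite."""

    polarity: Polarity
    theoretical_mz: float
    experimental_mz: float
    error_ppm: float
    status: str
    skeleton: SkeletonClass
    evidence: EvidenceBundle | None
    conflict: bool = False


@dataclass
class IdentificationRecord:
    """One output row: a metabolite with its observations and evidence."""

    label: str
    neutral_formula: ChemicalFormula
    skeleton_tag: str
    generation: int
    reaction_path: tuple[str, ...]
    rt_min: float
    observations: dict[Polarity, ModeObservation]
    status: str  # identified | potential
    skeleton_class: SkeletonClass
    conflict: bool = False

    @property
    def reaction(self) -> str:
        """Human-readable reaction annotation (Table-2 style)."""
        if not self.reaction_path:
            return "Prototype"
        return " + ".join(t.title() for t in self.reaction_path)


@dataclass
class PipelineConfig:
    ppm_tolerance: float = 5.0
    polarities: tuple[Polarity, ...] = (Polarity.pos, Polarity.neg)
    intensity_thresholds: dict = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_THRESHOLDS)
    )
    max_generations: int = 3
    random_seed: int = 0
    templates: tuple[ReactionTemplate, ...] | None = None
    msn_tolerance: float = NOMINAL_TOLERANCE
    rt_cluster_min: float = 0.3
    convention: IonConvention = IonConvention.physical
    use_mmdf: bool = True

    def __post_init__(self) -> None:
        if self.ppm_tolerance <= 0 or self.msn_tolerance <= 0:
            raise ValueError("tolerances must be positive")


def _center_mdf_templates(
    graph: DMCGraph, config: PipelineConfig
) -> list[MDFTemplate]:
    """Mass-defect filter windows around every current cluster center.

    Each center contributes its own prototype/glucuronide/sulfate
    triple, so the filter tracks the network as it grows — the multiple
    in "multiple mass defect filtering".
    """
    templates: dict[tuple[str, float], MDFTemplate] = {}
    for key in graph.centers:
        node = graph.node(key)
        for t in build_mdf_templates(node.formula):
            name = f"{t.name}@{node.formula.hill()}"
            templates[(name, t.center_mass)] = MDFTemplate(
                name=name,
                center_mass=t.center_mass,
                center_defect=t.center_defect,
                defect_halfwidth=t.defect_halfwidth,
                mass_halfwidth=t.mass_halfwidth,
            )
    return [templates[k] for k in sorted(templates)]


def _trees_for_hit(
    trees: Sequence[MSnTree], hit: ScreenHit, rt_window: float, mz_tol: float
) -> list[MSnTree]:
    out = []
    for tree in trees:
        if tree.polarity is not hit.polarity:
            continue
        if abs(tree.precursor_mz - hit.observed_mz) > mz_tol:
            continue
        if abs(tree.spectrum.retention_time - hit.rt_apex) > rt_window:
            continue
        out.append(tree)
    return out


def run_pipeline(
    runs: Sequence[Sequence[SpectrumRecord]],
    seed_formula: ChemicalFormula,
    config: PipelineConfig | None = None,
) -> tuple[list[IdentificationRecord], DMCGraph]:
    """Iterate predict -> screen -> confirm -> promote to fixpoint.

    ``runs`` is a list of scan lists (one per acquisition, single
    polarity each is typical).  Raises ``ValueError`` when no run
    contains MS^1 data.  Returns the report records and the final
    cluster graph.  Deterministic for a fixed config.
    """
    if config is None:
        config = PipelineConfig()
    if not any(s.ms_level == 1 for run in runs for s in run):
        raise ValueError("no MS^1 scans in any run")

    templates = (
        list(config.templates) if config.templates is not None else default_templates()
    )
    graph = DMCGraph(
        MetaboliteNode(formula=seed_formula, status=NodeStatus.identified)
    )
    all_trees: list[list[MSnTree]] = [build_msn_trees(run) for run in runs]

    resolved: dict = {}  # node key -> list[ConfirmationResult]
    for _round in range(config.max_generations + 1):
        graph = expand(
            graph, templates, max_generation=config.max_generations, hop_limit=1
        )
        mdf = _center_mdf_templates(graph, config) if config.use_mmdf else None
        new_confirmations: dict = {}
        for run, trees in zip(runs, all_trees):
            present = {s.polarity for s in run if s.ms_level == 1}
            for polarity in config.polarities:
                if polarity not in present:
                    continue
                hits = screen_graph(
                    run,
                    graph,
                    polarity,
                    tolerance_ppm=config.ppm_tolerance,
                    thresholds=config.intensity_thresholds,
                    templates=mdf,
                    convention=config.convention,
                )
                for hit in hits:
                    if hit.node_key in resolved:
                        continue
                    node = graph.node(hit.node_key)
                    hit_trees = _trees_for_hit(
                        trees, hit, config.rt_cluster_min, config.msn_tolerance
                    )
                    result = confirm_candidate(
                        hit,
                        hit_trees,
                        node.skeleton_tag,
                        node.reaction_path,
                        tolerance=config.msn_tolerance,
                    )
                    new_confirmations.setdefault(hit.node_key, []).append(result)
        if not new_confirmations:
            break
        newly_identified = []
        for key, results in new_confirmations.items():
            resolved[key] = results
            node = graph.node(key)
            if any(r.status == "identified" for r in results):
                newly_identified.append(key)
            else:
                node.status = NodeStatus.potential
        if not newly_identified:
            break
        promote_centers(graph, newly_identified)

    records = _build_records(graph, resolved, config)
    return records, graph


def _build_records(
    graph: DMCGraph, resolved: dict, config: PipelineConfig
) -> list[IdentificationRecord]:
    records: list[IdentificationRecord] = []
    order = sorted(
        resolved,
        key=lambda k: (
            graph.node(k).generation,
            graph.node(k).formula.hill(),
            graph.node(k).skeleton_tag,
        ),
    )
    for key in order:
        node = graph.node(key)
        results = sorted(resolved[key], key=lambda r: r.hit.rt_apex)
        # cluster by retention time: isomers separate, polarities merge
        clusters: list[list[ConfirmationResult]] = []
        for res in results:
            if (
                clusters
                and res.hit.rt_apex - clusters[-1][0].hit.rt_apex
                <= config.rt_cluster_min
            ):
                clusters[-1].append(res)
            else:
                clusters.append([res])
        multi = len(clusters) > 1
        for idx, cluster in enumerate(clusters):
            observations: dict[Polarity, ModeObservation] = {}
            for res in cluster:
                pol = res.hit.polarity
                obs = ModeObservation(
                    polarity=pol,
                    theoretical_mz=res.hit.predicted_mz,
                    experimental_mz=res.hit.observed_mz,
                    error_ppm=ppm_error(res.hit.observed_mz, res.hit.predicted_mz),
                    status=res.status,
                    skeleton=res.skeleton,
                    evidence=res.evidence,
                    conflict=res.conflict,
                )
                if pol not in observations or (
                    obs.status == "identified"
                    and observations[pol].status != "identified"
                ):
                    observations[pol] = obs
            status = (
                "identified"
                if any(o.status == "identified" for o in observations.values())
                else "potential"
            )
            skel = next(
                (
                    o.skeleton
                    for o in observations.values()
                    if o.status == "identified"
                ),
                next(iter(observations.values())).skeleton,
            )
            suffix = chr(ord("a") + idx) if multi else ""
            records.append(
                IdentificationRecord(
                    label=suffix,  # provisional; sequential labels assigned below
                    neutral_formula=node.formula,
                    skeleton_tag=node.skeleton_tag,
                    generation=node.generation,
                    reaction_path=node.reaction_path,
                    rt_min=cluster[0].hit.rt_apex,
                    observations=observations,
                    status=status,
                    skeleton_class=skel,
                    conflict=any(o.conflict for o in observations.values()),
                )
            )
    # sequential labels; isomer clusters keep an a/b/c suffix by rt
    for i, rec in enumerate(records):
        rec.label = f"M{i}{rec.label}"
    return records


def summarize(records: Sequence) -> dict[str, dict]:
    """Count distinct labels by status, reaction, skeleton and generation.

    Works on pipeline records and on fixture-table records alike: any
    object exposing ``label``, ``status`` and ``reaction`` (and
    optionally ``skeleton_class`` / ``generation``) is countable.
    Metabolites listed once per polarity are counted once.
    """
    by_status: dict[str, set] = {}
    by_reaction: dict[str, set] = {}
    by_skeleton: dict[str, set] = {}
    by_generation: dict[int, set] = {}
    for rec in records:
        label = rec.label
        by_status.setdefault(rec.status, set()).add(label)
        reaction = getattr(rec, "reaction", "") or ""
        if reaction:
            by_reaction.setdefault(reaction, set()).add(label)
        skel = getattr(rec, "skeleton_class", None)
        if skel is not None:
            by_skeleton.setdefault(
                skel.value if hasattr(skel, "value") else str(skel), set()
            ).add(label)
        gen = getattr(rec, "generation", None)
        if gen is not None:
            by_generation.setdefault(gen, set()).add(label)
    return {
        "status": {k: len(v) for k, v in sorted(by_status.items())},
        "reaction": {k: len(v) for k, v in sorted(by_reaction.items())},
        "skeleton": {k: len(v) for k, v in sorted(by_skeleton.items())},
        "generation": {k: len(v) for k, v in sorted(by_generation.items())},
    }


_REPORT_HEADER = (
    "label\tion_mode\trt_min\tformula\ttheoretical_mz\texperimental_mz\t"
    "error_ppm\tstatus\tskeleton_class\tgeneration\treaction"
)


def write_report(
    records: Sequence[IdentificationRecord],
    graph: DMCGraph | None,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Emit the identification TSV, the cluster GraphML and a summary.

    The TSV mirrors the published-table layout: one line per polarity
    observation, m/z to 5 decimals, ppm to 1 decimal (half away from
    zero).  Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    tsv = out_dir / "identifications.tsv"
    with open(tsv, "w") as fh:
        fh.write(_REPORT_HEADER + "\n")
        for rec in records:
            for pol in (Polarity.neg, Polarity.pos):
                obs = rec.observations.get(pol)
                if obs is None:
                    continue
                fh.write(
                    "\t".join(
                        [
                            rec.label,
                            "N" if pol is Polarity.neg else "P",
                            f"{rec.rt_min:.2f}",
                            rec.neutral_formula.hill(),
                            f"{round_half_away(obs.theoretical_mz, 5):.5f}",
                            f"{round_half_away(obs.experimental_mz, 5):.5f}",
                            f"{round_half_away(obs.error_ppm, 1):.1f}",
                            rec.status,
                            rec.skeleton_class.value,
                            str(rec.generation),
                            rec.reaction,
                        ]
                    )
                    + "\n"
                )
    paths["identifications"] = tsv

    if graph is not None:
        gml = out_dir / "dmc.graphml"
        graph.write_graphml(gml)
        paths["graph"] = gml

    summary = out_dir / "summary.txt"
    s = summarize(records)
    with open(summary, "w") as fh:
        fh.write("Drug metabolite cluster mining summary\n")
        for section, counts in s.items():
            fh.write(f"\n[{section}]\n")
            for k, v in counts.items():
                fh.write(f"{k}\t{v}\n")
        if graph is not None:
            fh.write("\n[centers per generation]\n")
            for gen, n in generation_summary(graph).items():
                fh.write(f"{gen}\t{n}\n")
    paths["summary"] = summary
    return paths


def read_records_tsv(path: str | Path) -> list[dict]:
    """Read back a written identification TSV as a list of row dicts."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or lines[0] != _REPORT_HEADER:
        raise ValueError(f"{path}: not an identification report")
    header = lines[0].split("\t")
    return [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]
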