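"""Biotransformation templates and metabolite-cluster network expansion.

A reaction template is an elemental delta (gain/loss) with applicability
constraints.  Starting from a prototype drug formula, templates are
applied breadth-first to build a generation-ranked, directed multigraph
of predicted metabolites: the drug metabolite cluster (DMC).  Nodes that
are later confirmed by MS^n evidence are promoted to *cluster centers*
and become seeds for the next expansion round, so the network grows
iteratively — primary, secondary, tertiary clusters — rather than only
radiating one hop from the parent drug.

Node identity is (elemental formula, skeleton tag).  Hydrogenation to a
flavanone and rearrangement to a chalcone both add H2; they are kept as
distinct nodes because their MS^2 diagnostic ions differ, and conflating
them would collapse isomeric metabolite classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import networkx as nx

from .formula import ChemicalFormula, FormulaError, monoisotopic_mass, parse_formula

__all__ = [
    "ReactionPhase",
    "ReactionTemplate",
    "InapplicableTemplate",
    "NodeStatus",
    "MetaboliteNode",
    "DMCGraph",
    "apply_reaction",
    "default_templates",
    "expand",
    "promote_centers",
    "generation_summary",
]


class ReactionPhase(str, Enum):
    phase1 = "phase1"
    phase2 = "phase2"
    rearrangement = "rearrangement"


class InapplicableTemplate(ValueError):
    """Template loss exceeds available atoms: the reaction cannot occur."""


@dataclass(frozen=True)
class ReactionTemplate:
    """An elemental gain/loss with applicability metadata.

    ``terminal`` marks phase-II conjugations whose products are not
    expanded further by default; ``max_applications`` caps how often the
    same template may recur along one reaction path; ``skeleton_tag``, if
    set, retags the product (flavanone / chalcone formation).
    """

    name: str
    gain: ChemicalFormula | None = None
    loss: ChemicalFormula | None = None
    phase: ReactionPhase = ReactionPhase.phase1
    terminal: bool = False
    max_applications: int = 2
    skeleton_tag: str | None = None

    def __post_init__(self) -> None:
        if self.gain is None and self.loss is None:
            raise ValueError(f"template {self.name!r}: gain and loss both empty")
        if self.max_applications < 1:
            raise ValueError(f"template {self.name!r}: max_applications < 1")

    def delta_mass(self) -> float:
        d = 0.0
        if self.gain is not None:
            d += monoisotopic_mass(self.gain)
        if self.loss is not None:
            d -= monoisotopic_mass(self.loss)
        return d


class NodeStatus(str, Enum):
    predicted = "predicted"
    identified = "identified"
    potential = "potential"


@dataclass
class MetaboliteNode:
    """One predicted or confirmed metabolite in the cluster graph."""

    formula: ChemicalFormula
    skeleton_tag: str = "flavone"
    generation: int = 0
    reaction_path: tuple[str, ...] = ()
    parent: tuple[ChemicalFormula, str] | None = None
    status: NodeStatus = NodeStatus.predicted
    expandable: bool = True

    @property
    def key(self) -> tuple[ChemicalFormula, str]:
        return (self.formula, self.skeleton_tag)

    def __post_init__(self) -> None:
        if self.generation != len(self.reaction_path):
            raise ValueError("generation must equal reaction-path length")


class DMCGraph:
    """Directed multigraph of metabolites with generation ranks and centers.

    Thin wrapper over :class:`networkx.MultiDiGraph`; node keys are
    (formula, skeleton tag) pairs, edge keys are template names.
    """

    def __init__(self, root: MetaboliteNode):
        self.graph = nx.MultiDiGraph()
        self.root = root.key
        self.graph.add_node(root.key, node=root)
        self.centers: set[tuple[ChemicalFormula, str]] = {root.key}

    def node(self, key) -> MetaboliteNode:
        try:
            return self.graph.nodes[key]["node"]
        except KeyError:
            raise KeyError(f"node {key!r} not in graph") from None

    def nodes(self) -> list[MetaboliteNode]:
        return [self.graph.nodes[k]["node"] for k in self.graph.nodes]

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def add_product(
        self, parent: MetaboliteNode, template: ReactionTemplate, formula: ChemicalFormula
    ) -> MetaboliteNode:
        tag = template.skeleton_tag or parent.skeleton_tag
        key = (formula, tag)
        if key not in self.graph:
            node = MetaboliteNode(
                formula=formula,
                skeleton_tag=tag,
                generation=parent.generation + 1,
                reaction_path=parent.reaction_path + (template.name,),
                parent=parent.key,
                expandable=not template.terminal,
            )
            self.graph.add_node(key, node=node)
        node = self.node(key)
        if not self.graph.has_edge(parent.key, key, key=template.name):
            self.graph.add_edge(parent.key, key, key=template.name, template=template.name)
        return node

    # -- export ---------------------------------------------------------
    def to_networkx(self) -> nx.MultiDiGraph:
        """Plain-attribute copy suitable for GraphML/DOT serialisation."""
        g = nx.MultiDiGraph()
        for key in self.graph.nodes:
            n = self.node(key)
            g.add_node(
                f"{n.formula.hill()}|{n.skeleton_tag}",
                formula=n.formula.hill(),
                skeleton=n.skeleton_tag,
                generation=n.generation,
                status=n.status.value,
                center=key in self.centers,
                reaction_path=" + ".join(n.reaction_path),
            )
        for u, v, k in self.graph.edges(keys=True):
            nu, nv = self.node(u), self.node(v)
            g.add_edge(
                f"{nu.formula.hill()}|{nu.skeleton_tag}",
                f"{nv.formula.hill()}|{nv.skeleton_tag}",
                key=k,
                template=k,
            )
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def write_dot(self, path) -> None:
        g = self.to_networkx()
        lines = ["digraph DMC {"]
        for n, d in g.nodes(data=True):
            lines.append(
                f'  "{n}" [label="{d["formula"]}\\n{d["skeleton"]}" '
                f'generation={d["generation"]}];'
            )
        for u, v, k in g.edges(keys=True):
            lines.append(f'  "{u}" -> "{v}" [label="{k}"];')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    def node_table(self) -> list[dict]:
        rows = []
        for n in sorted(self.nodes(), key=lambda n: (n.generation, n.formula.hill(), n.skeleton_tag)):
            rows.append(
                {
                    "formula": n.formula.hill(),
                    "skeleton": n.skeleton_tag,
                    "generation": n.generation,
                    "status": n.status.value,
                    "center": n.key in self.centers,
                    "reaction_path": " + ".join(n.reaction_path),
                }
            )
        return rows


def apply_reaction(f: ChemicalFormula, t: ReactionTemplate) -> ChemicalFormula:
    """Apply one template: result = f + gain - loss.

    Raises :class:`InapplicableTemplate` when the loss would drive any
    element count negative — an explicit signal, never a silent skip.
    """
    result = f
    if t.gain is not None:
        result = result + t.gain
    if t.loss is not None:
        try:
            result = result - t.loss
        except FormulaError as exc:
            raise InapplicableTemplate(
                f"template {t.name!r} inapplicable to {f.hill()}: {exc}"
            ) from exc
    return result


def _f(text: str) -> ChemicalFormula:
    return parse_formula(text)


def default_templates() -> list[ReactionTemplate]:
    """The stock template library for flavonoid metabolism.

    Phase-I redox/alkylation reactions, H2 additions producing flavanone
    or chalcone skeletons, two ring-cleavage losses, and the two phase-II
    conjugations (terminal, once per path).  Demethylation is allowed up
    to three times per path; everything else at most twice.
    """
    P1, P2, RE = ReactionPhase.phase1, ReactionPhase.phase2, ReactionPhase.rearrangement
    return [
        ReactionTemplate("oxidation", gain=_f("O"), phase=P1),
        ReactionTemplate("di-oxidation", gain=_f("O2"), phase=P1, max_applications=1),
        ReactionTemplate("methylation", gain=_f("CH2"), phase=P1),
        ReactionTemplate("demethylation", loss=_f("CH2"), phase=P1, max_applications=3),
        ReactionTemplate("methoxylation", gain=_f("CH2O"), phase=P1),
        ReactionTemplate("demethoxylation", loss=_f("CH2O"), phase=P1),
        ReactionTemplate(
            "flavanone formation", gain=_f("H2"), phase=RE,
            skeleton_tag="flavanone", max_applications=1,
        ),
        ReactionTemplate(
            "chalcone formation", gain=_f("H2"), phase=RE,
            skeleton_tag="chalcone", max_applications=1,
        ),
        ReactionTemplate("carbonyl loss", loss=_f("CO"), phase=P1, max_applications=1),
        ReactionTemplate("methane loss", loss=_f("CH4"), phase=P1, max_applications=1),
        ReactionTemplate(
            "glucuronidation", gain=_f("C6H8O6"), phase=P2,
            terminal=True, max_applications=1,
        ),
        ReactionTemplate(
            "sulfation", gain=_f("SO3"), phase=P2,
            terminal=True, max_applications=1,
        ),
    ]


def expand(
    seed: ChemicalFormula | DMCGraph,
    templates: Sequence[ReactionTemplate] | None = None,
    max_generation: int = 3,
    hop_limit: int | None = None,
) -> DMCGraph:
    """Breadth-first template closure from the current cluster centers.

    Given a bare formula, a new graph is rooted at it (generation 0) and
    the root is the sole center.  Given an existing graph, expansion
    resumes from its centers — this is how promoted nodes spawn the next
    cluster generation.

    The closure is an exact breadth-first enumeration of legal template
    sequences out of each expandable center: a sequence is legal when
    every step is elementally applicable, no template recurs beyond its
    ``max_applications`` along the whole path (the center's own history
    counts), terminal templates appear only as the final step, and the
    absolute generation never exceeds ``max_generation``.  ``hop_limit``
    caps sequence length per center; it defaults to unlimited for a
    fresh seed (full closure to ``max_generation``) and to one hop when
    resuming an existing graph, so that after center promotion the next
    generation appears only around the promoted centers — one round of
    the iterative workflow.  Duplicate (formula, tag)
    products merge into one node that keeps every incoming edge; a
    node's stored path is a shortest one.  Deterministic and independent
    of template iteration order (templates are sorted by name).
    """
    if max_generation < 1:
        raise ValueError("max_generation must be >= 1")
    if templates is None:
        templates = default_templates()
    templates = sorted(templates, key=lambda t: t.name)

    if isinstance(seed, DMCGraph):
        g = seed
        if hop_limit is None:
            hop_limit = 1
    else:
        g = DMCGraph(MetaboliteNode(formula=seed, status=NodeStatus.identified))

    # Lower-generation centers first so a shared product is attributed to
    # its shortest reaction path.
    centers = [g.node(k) for k in g.centers]
    centers.sort(key=lambda n: (n.generation, n.formula.hill(), n.skeleton_tag))
    for center in centers:
        if not center.expandable:
            continue
        depth = max_generation - center.generation
        if hop_limit is not None:
            depth = min(depth, hop_limit)
        if depth <= 0:
            continue
        # Breadth-first over sequences: frontier of (node, path-from-root).
        frontier: list[tuple[MetaboliteNode, tuple[str, ...]]] = [
            (center, center.reaction_path)
        ]
        for _ in range(depth):
            next_frontier: list[tuple[MetaboliteNode, tuple[str, ...]]] = []
            for parent, path in frontier:
                for t in templates:
                    if path.count(t.name) >= t.max_applications:
                        continue
                    try:
                        product = apply_reaction(parent.formula, t)
                    except InapplicableTemplate:
                        continue
                    node = g.add_product(parent, t, product)
                    if not t.terminal:
                        next_frontier.append((node, path + (t.name,)))
            frontier = next_frontier
    return g


def promote_centers(
    g: DMCGraph, confirmed: Iterable[tuple[ChemicalFormula, str] | MetaboliteNode]
) -> DMCGraph:
    """Mark confirmed nodes as identified cluster centers.

    Promoted nodes become expansion-eligible seeds for the next
    :func:`expand` round.  Unknown nodes raise ``KeyError``.
    """
    for item in confirmed:
        key = item.key if isinstance(item, MetaboliteNode) else item
        node = g.node(key)
        node.status = NodeStatus.identified
        g.centers.add(key)
    return g


def generation_summary(g: DMCGraph) -> dict[int, int]:
    """Count cluster centers per generation, excluding the generation-0 root."""
    out: dict[int, int] = {}
    for key in g.centers:
        n = g.node(key)
        if n.generation == 0:
            continue
        out[n.generation] = out.get(n.generation, 0) + 1
    return dict(sorted(out.items()))
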