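"""Reaction templates and metabolite-cluster network expansion."""

import itertools

import pytest

from dmcminer.biotransform import (
    DMCGraph,
    InapplicableTemplate,
    MetaboliteNode,
    NodeStatus,
    ReactionTemplate,
    apply_reaction,
    default_templates,
    expand,
    generation_summary,
    promote_centers,
)
from dmcminer.formula import monoisotopic_mass, parse_formula


def by_name(name):
    return next(t for t in default_templates() if t.name == name)


# -- apply_reaction --------------------------------------------------------


@pytest.mark.parametrize(
    "template,product",
    [
        ("glucuronidation", "C25H26O13"),
        ("demethylation", "C18H16O7"),
        ("methoxylation", "C20H20O8"),
        ("flavanone formation", "C19H20O7"),
        ("sulfation", "C19H18O10S"),
    ],
)
def test_apply_reaction_products(htf, template, product):
    assert apply_reaction(htf, by_name(template)) == parse_formula(product)


def test_apply_reaction_signals_inapplicability(htf):
    big_loss = ReactionTemplate("bulk demethylation", loss=parse_formula("C20H40"))
    with pytest.raises(InapplicableTemplate):
        apply_reaction(htf, big_loss)


def test_template_mass_delta_matches_formula_arithmetic(htf):
    for t in default_templates():
        try:
            product = apply_reaction(htf, t)
        except InapplicableTemplate:
            continue
        assert monoisotopic_mass(product) - monoisotopic_mass(htf) == pytest.approx(
            t.delta_mass(), abs=1e-9
        )


def test_default_template_inventory():
    names = {t.name for t in default_templates()}
    assert {
        "oxidation",
        "di-oxidation",
        "methylation",
        "demethylation",
        "methoxylation",
        "demethoxylation",
        "flavanone formation",
        "chalcone formation",
        "carbonyl loss",
        "methane loss",
        "glucuronidation",
        "sulfation",
    } <= names
    conj = [t for t in default_templates() if t.name in ("glucuronidation", "sulfation")]
    assert all(t.terminal and t.max_applications == 1 for t in conj)


# -- expansion -------------------------------------------------------------


def three_templates():
    return [by_name("oxidation"), by_name("demethylation"), by_name("sulfation")]


def test_single_hop_expansion(htf):
    g = expand(htf, three_templates(), max_generation=1)
    assert len(g) == 4
    gens = {n.generation for n in g.nodes()}
    assert gens == {0, 1}


def test_demethylation_chain_limited_by_hydrogens(htf):
    t = ReactionTemplate("demethylation", loss=parse_formula("CH2"), max_applications=9)
    g = expand(htf, [t], max_generation=9)
    # 18 H supports 9 CH2 losses: root + 9 chain nodes
    assert len(g) == 10
    deepest = max(g.nodes(), key=lambda n: n.generation)
    assert deepest.generation == 9
    assert deepest.formula == parse_formula("C10O7")


def enumeration_oracle(seed, templates, depth):
    """Independent oracle: all legal template sequences, applied directly."""
    out = {(seed.hill(), "flavone")}
    def rec(formula, tag, path):
        if len(path) >= depth:
            return
        for t in templates:
            if path.count(t.name) >= t.max_applications:
                continue
            try:
                product = apply_reaction(formula, t)
            except InapplicableTemplate:
                continue
            new_tag = t.skeleton_tag or tag
            out.add((product.hill(), new_tag))
            if not t.terminal:
                rec(product, new_tag, path + [t.name])
    rec(seed, "flavone", [])
    return out


@pytest.mark.parametrize("depth", [1, 2, 3])
def test_expansion_equals_sequence_enumeration(htf, depth):
    templates = default_templates()
    g = expand(htf, templates, max_generation=depth)
    got = {(n.formula.hill(), n.skeleton_tag) for n in g.nodes()}
    assert got == enumeration_oracle(htf, templates, depth)


def test_expansion_order_independence(htf):
    templates = default_templates()
    base = expand(htf, templates, max_generation=2)
    for perm in (list(reversed(templates)), templates[6:] + templates[:6]):
        g = expand(htf, perm, max_generation=2)
        assert {n.key for n in g.nodes()} == {n.key for n in base.nodes()}
        assert set(g.graph.edges(keys=True)) == set(base.graph.edges(keys=True))


def test_expansion_idempotence(htf):
    g = expand(htf, three_templates(), max_generation=2)
    n_nodes, n_edges = len(g), g.graph.number_of_edges()
    g = expand(g, three_templates(), max_generation=2)
    assert (len(g), g.graph.number_of_edges()) == (n_nodes, n_edges)


def test_mass_bookkeeping_along_paths(htf):
    g = expand(htf, default_templates(), max_generation=3)
    deltas = {t.name: t.delta_mass() for t in default_templates()}
    seed_mass = monoisotopic_mass(htf)
    for node in g.nodes():
        expected = seed_mass + sum(deltas[t] for t in node.reaction_path)
        assert monoisotopic_mass(node.formula) == pytest.approx(expected, abs=1e-9)


def test_isomeric_skeletons_stay_distinct(htf):
    """Flavanone and chalcone formation both add H2 but must not merge."""
    g = expand(htf, default_templates(), max_generation=1)
    h2_nodes = [n for n in g.nodes() if n.formula == parse_formula("C19H20O7")]
    assert {n.skeleton_tag for n in h2_nodes} == {"flavanone", "chalcone"}


def test_terminal_conjugates_not_expanded(htf):
    g = expand(htf, default_templates(), max_generation=3)
    for node in g.nodes():
        if node.reaction_path and node.reaction_path[-1] in (
            "glucuronidation",
            "sulfation",
        ):
            assert not node.expandable
        # conjugation never occurs mid-path
        for t in ("glucuronidation", "sulfation"):
            if t in node.reaction_path:
                assert node.reaction_path[-1] == t


# -- promotion and summaries -----------------------------------------------


def test_promote_then_expand_grows_neighbourhood(htf):
    g = expand(htf, three_templates(), max_generation=1)
    oxidised = (parse_formula("C19H18O8"), "flavone")
    promote_centers(g, [oxidised])
    g = expand(g, three_templates(), max_generation=2)
    gen2 = [n for n in g.nodes() if n.generation == 2]
    assert gen2
    assert all(n.parent == oxidised for n in gen2)


def test_promote_nothing_is_fixpoint(htf):
    g = expand(htf, three_templates(), max_generation=1)
    before = {n.key for n in g.nodes()}
    g = expand(g, three_templates(), max_generation=1)
    assert {n.key for n in g.nodes()} == before


def test_promote_unknown_node_raises(htf):
    g = expand(htf, three_templates(), max_generation=1)
    with pytest.raises(KeyError):
        promote_centers(g, [(parse_formula("C5H5N5"), "flavone")])


def test_generation_summary_counts_centers(htf):
    g = expand(htf, three_templates(), max_generation=1)
    assert generation_summary(g) == {}
    promote_centers(g, [n.key for n in g.nodes() if n.generation == 1])
    assert generation_summary(g) == {1: 3}


def test_graph_exports(tmp_path, htf):
    g = expand(htf, three_templates(), max_generation=1)
    gml = tmp_path / "dmc.graphml"
    dot = tmp_path / "dmc.dot"
    g.write_graphml(gml)
    g.write_dot(dot)
    import networkx as nx

    back = nx.read_graphml(gml)
    assert back.number_of_nodes() == len(g)
    assert "digraph" in dot.read_text()
    rows = g.node_table()
    assert len(rows) == len(g) and rows[0]["generation"] == 0
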