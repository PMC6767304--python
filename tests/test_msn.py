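"""Neutral-loss detection, diagnostic ions and skeleton classification."""

import pytest

from dmcminer.formula import nominal_cation_mz, parse_formula
from dmcminer.msn import (
    SkeletonClass,
    classify_skeleton,
    confirm_candidate,
    default_dpi_rules,
    default_loss_rules,
    detect_neutral_losses,
    match_dpis,
    methyl_ladder_depth,
    screen_methyl_losses,
)
from dmcminer.screening import ScreenHit
from dmcminer.spectra import MSnTree, Peak, Polarity, SpectrumRecord


def spectrum(level, prec, peaks, polarity=Polarity.pos):
    return SpectrumRecord(
        ms_level=level,
        polarity=polarity,
        retention_time=5.0,
        peaks=[Peak(float(mz), float(i)) for mz, i in peaks],
        precursor_mz=float(prec),
    )


def tree(level2_peaks, prec, ms3=None):
    t = MSnTree(spectrum(2, prec, level2_peaks))
    if ms3 is not None:
        prec3, peaks3 = ms3
        t.children.append(MSnTree(spectrum(3, prec3, peaks3)))
    return t


# -- rule self-consistency -------------------------------------------------


def test_loss_rules_nominal_equals_rounded_exact():
    for rule in default_loss_rules():
        assert rule.nominal == round(rule.exact_mass)


def test_dpi_rules_match_their_fragment_formulas():
    """Each rule's nominal m/z equals the cation m/z of its formula."""
    expected = {"C8H7O3": 151, "C10H11O5": 211, "C12H13O4": 221, "C9H9O5": 197}
    listed = {}
    for rule in default_dpi_rules():
        for f, nm in zip(rule.fragment_formulas, rule.nominal_mzs):
            listed[f.hill()] = nm
    assert listed == expected
    for text, nm in expected.items():
        assert nominal_cation_mz(parse_formula(text)) == nm


# -- neutral losses --------------------------------------------------------


def test_methyl_radical_chain():
    t = tree([(344, 100), (329, 24)], 359)
    names = {a.rule_name for a in detect_neutral_losses(t)}
    assert "CH3 radical" in names
    assert methyl_ladder_depth(t) == 2


def test_glucuronide_loss_from_533():
    t = tree([(357, 100)], 533)
    assert {a.rule_name for a in detect_neutral_losses(t)} == {"glucuronyl"}


def test_sulfate_loss_from_453():
    t = tree([(373, 100)], 453)
    assert {a.rule_name for a in detect_neutral_losses(t)} == {"SO3"}


def test_loss_detection_invariant_to_order_and_scaling():
    a = tree([(344, 100), (329, 24), (331, 5)], 359)
    b = tree([(331, 50), (329, 240), (344, 1000)], 359)
    key = lambda ann: (ann.rule_name, ann.fragment_mz)
    assert sorted(map(key, detect_neutral_losses(a))) == sorted(
        map(key, detect_neutral_losses(b))
    )


# -- methyl-loss screening -------------------------------------------------


@pytest.mark.parametrize(
    "prec,peaks,expected",
    [
        (359, [(344, 100)], True),   # n = 1
        (359, [(329, 100)], True),   # n = 2
        (359, [(340, 100)], False),
        (533, [(357, 100)], False),  # 176 is not a multiple of 15
    ],
)
def test_screen_methyl_losses(prec, peaks, expected):
    assert screen_methyl_losses(spectrum(2, prec, peaks)) is expected


def test_flavone_standards_show_methyl_ladder(table1):
    """Flavone reference standards lose CH3 radicals; flavanone/chalcone
    standards show the 211 or 221 retro-Diels-Alder ion instead."""
    flavones = {"P-1", "P-2", "P-6", "P-7", "P-9"}
    for rec in table1:
        t = rec.msn_tree()
        if rec.label in flavones:
            assert screen_methyl_losses(t.spectrum), rec.label
        else:
            nominals = {m.nominal_mz for m in match_dpis(t)}
            assert nominals & {211, 221}, rec.label


# -- DPI matching ----------------------------------------------------------


def test_match_dpis_reports_offset_x():
    t = tree([(151, 10), (165, 5), (344, 100)], 359)
    flavone = [m for m in match_dpis(t) if m.skeleton is SkeletonClass.polymethoxyflavone]
    assert {(m.nominal_mz, m.offset_x) for m in flavone} == {(151, 0), (165, 14)}


def test_match_dpis_base_peak_flag():
    t = tree([(211, 100), (196, 20)], 361)
    m211 = next(m for m in match_dpis(t) if m.nominal_mz == 211)
    assert m211.is_base_peak


# -- skeleton classification -----------------------------------------------


def test_classify_flavanone_tree():
    t = tree([(211, 100), (177, 16)], 361, ms3=(211, [(196, 100)]))
    cls, ev = classify_skeleton(t)
    assert cls is SkeletonClass.polymethoxyflavanone


def test_classify_chalcone_tree():
    t = tree([(221, 100), (197, 17)], 377)
    cls, _ = classify_skeleton(t)
    assert cls is SkeletonClass.polymethoxychalcone


def test_classify_sulfate_tree():
    t = tree([(373, 100)], 453, ms3=(373, [(358, 100)]))
    cls, ev = classify_skeleton(t)
    assert cls is SkeletonClass.sulfate_conjugate
    assert ev.conjugate_loss == "SO3"


def test_classify_glucuronide_recurses_into_aglycone():
    t = tree([(357, 100)], 533, ms3=(357, [(342, 100), (327, 20)]))
    cls, ev = classify_skeleton(t)
    assert cls is SkeletonClass.glucuronide_conjugate
    assert ev.inner_skeleton is SkeletonClass.polymethoxyflavone


def test_classify_flavone_needs_ladder_depth_two():
    single = tree([(344, 100)], 359)
    assert classify_skeleton(single)[0] is SkeletonClass.unclassified
    double = tree([(344, 100), (329, 30)], 359)
    assert classify_skeleton(double)[0] is SkeletonClass.polymethoxyflavone


def test_classification_on_fixture_trees(table2):
    """Worked examples: representative metabolites classify as reported."""
    expected = {
        ("M14", Polarity.pos): SkeletonClass.polymethoxyflavanone,
        ("M34", Polarity.pos): SkeletonClass.polymethoxychalcone,
        ("M72", Polarity.neg): SkeletonClass.sulfate_conjugate,
        ("M78", Polarity.neg): SkeletonClass.glucuronide_conjugate,
        ("M0", Polarity.neg): SkeletonClass.polymethoxyflavone,
    }
    for (label, pol), cls in expected.items():
        rec = next(r for r in table2 if r.label == label and r.ion_mode is pol)
        assert classify_skeleton(rec.msn_tree())[0] is cls, label


# -- candidate confirmation ------------------------------------------------


def make_hit(formula="C25H26O13"):
    return ScreenHit(
        node_key=(parse_formula(formula), "flavone"),
        predicted_mz=533.12903,
        observed_mz=533.12878,
        rt_apex=7.49,
        apex_intensity=50000.0,
        polarity=Polarity.neg,
    )


def test_confirm_glucuronide_candidate():
    t = tree([(357, 100)], 533, ms3=(357, [(342, 100), (327, 20)]))
    res = confirm_candidate(make_hit(), [t], "flavone", ("glucuronidation",))
    assert res.status == "identified"
    assert res.skeleton is SkeletonClass.glucuronide_conjugate


def test_confirm_without_tree_is_potential():
    res = confirm_candidate(make_hit(), [], "flavone", ("glucuronidation",))
    assert res.status == "potential" and not res.conflict


def test_confirm_contradictory_evidence_flags_conflict():
    flavanone_tree = tree([(211, 100)], 533)
    res = confirm_candidate(
        make_hit(), [flavanone_tree], "flavone", ("glucuronidation",)
    )
    assert res.status == "potential" and res.conflict


def test_confirm_unmatched_peaks_is_potential_conflict():
    noise = tree([(123.4, 100), (222.7, 10)], 533)
    res = confirm_candidate(make_hit(), [noise], "flavone", ("glucuronidation",))
    assert res.status == "potential" and res.conflict
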