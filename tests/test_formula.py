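"""Formula parsing, mass arithmetic, ion conventions and decomposition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dmcminer.constants import PROTON_MASS
from dmcminer.formula import (
    ChemicalFormula,
    DecompositionConstraints,
    FormulaError,
    IonConvention,
    IonMode,
    cation_mz,
    decompose_mass,
    ion_mz,
    mass_defect,
    monoisotopic_mass,
    nominal_cation_mz,
    parse_formula,
    ppm_error,
    rdb,
)
from conftest import brute_force_decompose


# -- parsing ---------------------------------------------------------------


@pytest.mark.parametrize(
    "text,expected",
    [
        ("C19H18O7", {"C": 19, "H": 18, "O": 7}),
        ("H2O", {"H": 2, "O": 1}),
        ("C_19_H_18_O_7_", {"C": 19, "H": 18, "O": 7}),
        ("C_20_ H_21_O_8_", {"C": 20, "H": 21, "O": 8}),
        ("C_18_H_1__5_O_8_", {"C": 18, "H": 15, "O": 8}),
        ("CH3", {"C": 1, "H": 3}),
    ],
)
def test_parse_formula(text, expected):
    assert parse_formula(text).as_dict() == expected


@pytest.mark.parametrize("bad", ["C19H18Xx7", "", "19C", "C-3"])
def test_parse_formula_rejects_malformed(bad):
    with pytest.raises(FormulaError):
        parse_formula(bad)


def test_formula_roundtrips_through_hill_format():
    for text in ("C19H18O7", "C6H8O6", "SO3", "C19H17O11S"):
        f = parse_formula(text)
        assert parse_formula(f.hill()) == f


def test_formula_invariants():
    with pytest.raises(FormulaError):
        ChemicalFormula({})
    with pytest.raises(FormulaError):
        ChemicalFormula({"C": -1})


# -- masses and ions -------------------------------------------------------


@pytest.mark.parametrize(
    "text,mass",
    [
        ("C19H18O7", 358.10525),  # prototype neutral
        ("H", 1.00783),
        ("C6H8O6", 176.03209),  # glucuronyl moiety
    ],
)
def test_monoisotopic_mass(text, mass):
    assert monoisotopic_mass(parse_formula(text)) == pytest.approx(mass, abs=1e-5)


@pytest.mark.parametrize(
    "text,mode,convention,mz",
    [
        ("C21H24O8", IonMode.protonated_pos, IonConvention.physical, 405.15439),
        ("C20H20O8", IonMode.protonated_pos, IonConvention.physical, 389.12309),
        ("C19H18O7", IonMode.deprotonated_neg, IonConvention.physical, 357.09798),
        # tabulation convention: M - H(atom) - electron
        ("C19H18O7", IonMode.deprotonated_neg, IonConvention.paper_negative, 357.09688),
    ],
)
def test_ion_mz_conventions(text, mode, convention, mz):
    assert ion_mz(parse_formula(text), mode, convention) == pytest.approx(mz, abs=1e-5)


def test_ppm_error_reproduces_reported_errors():
    # printed experimental/theoretical pairs for two demethylated isomers
    assert round(ppm_error(345.09546, 345.09687), 1) == -4.1
    assert round(ppm_error(345.09558, 345.09687), 1) == -3.7
    assert ppm_error(500.0, 500.0) == 0.0
    with pytest.raises(ValueError):
        ppm_error(100.0, 0.0)


@pytest.mark.parametrize(
    "text,value",
    [("C19H18O7", 11.0), ("C6H6", 4.0), ("H2O", 0.0)],
)
def test_rdb(text, value):
    assert rdb(parse_formula(text)) == value


def test_mass_defect():
    assert mass_defect(534.13734) == pytest.approx(137.34, abs=0.01)
    assert mass_defect(438.06207) == pytest.approx(62.07, abs=0.01)
    assert mass_defect(100.0) == 0.0
    with pytest.raises(ValueError):
        mass_defect(-1.0)


@pytest.mark.parametrize(
    "text,nominal",
    [("C8H7O3", 151), ("C10H11O5", 211), ("C12H13O4", 221), ("C9H9O5", 197)],
)
def test_diagnostic_cation_nominal_mz(text, nominal):
    assert nominal_cation_mz(parse_formula(text)) == nominal


# -- property tests --------------------------------------------------------

formula_strategy = st.builds(
    lambda c, h, o, n, s: ChemicalFormula(
        {k: v for k, v in {"C": c, "H": h, "O": o, "N": n, "S": s}.items() if v}
    ),
    st.integers(1, 30),
    st.integers(0, 50),
    st.integers(0, 20),
    st.integers(0, 3),
    st.integers(0, 2),
)


@settings(derandomize=True, max_examples=50)
@given(formula_strategy, formula_strategy)
def test_mass_additivity(f1, f2):
    assert monoisotopic_mass(f1 + f2) == pytest.approx(
        monoisotopic_mass(f1) + monoisotopic_mass(f2), abs=1e-9
    )


@settings(derandomize=True, max_examples=50)
@given(formula_strategy)
def test_ion_convention_consistency(f):
    pos = ion_mz(f, IonMode.protonated_pos)
    neg = ion_mz(f, IonMode.deprotonated_neg, IonConvention.physical)
    assert pos - neg == pytest.approx(2 * PROTON_MASS, abs=1e-9)


@settings(derandomize=True, max_examples=50)
@given(
    st.floats(100.0, 1000.0, allow_nan=False),
    st.floats(100.0, 1000.0, allow_nan=False),
)
def test_ppm_error_antisymmetry_identity(a, b):
    # (a-b)/b = -[(b-a)/a] * a/b
    assert ppm_error(a, b) == pytest.approx(-ppm_error(b, a) * a / b, rel=1e-9)


@settings(derandomize=True, max_examples=25)
@given(formula_strategy)
def test_decomposition_recovers_own_formula(f):
    if rdb(f) < 0 or rdb(f) > 15:
        return
    target = ion_mz(f, IonMode.protonated_pos)
    assert f in decompose_mass(target, IonMode.protonated_pos)


# -- decomposition vs brute force ------------------------------------------


def test_decompose_below_any_formula_mass_is_empty():
    assert decompose_mass(1.0, IonMode.protonated_pos) == []


def test_decompose_matches_brute_force_oracle(decomposition_grid):
    """Exact set equality against full-grid enumeration on random targets."""
    rng = np.random.default_rng(20240917)
    targets = rng.uniform(120.0, 650.0, size=20)
    for target in targets:
        for mode, tag in ((IonMode.protonated_pos, "pos"), (IonMode.deprotonated_neg, "neg")):
            got = {f.counts for f in decompose_mass(float(target), mode)}
            expected = brute_force_decompose(decomposition_grid, float(target), tag)
            assert got == expected, f"mismatch at {target:.5f} ({tag})"


def test_decompose_ordering_is_ppm_then_heteroatoms():
    cands = decompose_mass(359.11218, IonMode.protonated_pos)
    errs = [abs(ppm_error(359.11218, ion_mz(c, IonMode.protonated_pos))) for c in cands]
    assert errs == sorted(errs)
    assert parse_formula("C19H18O7") in cands


def test_decompose_tolerance_monotonicity():
    narrow = decompose_mass(
        373.12822, IonMode.protonated_pos, DecompositionConstraints(tolerance_ppm=2.0)
    )
    wide = decompose_mass(
        373.12822, IonMode.protonated_pos, DecompositionConstraints(tolerance_ppm=5.0)
    )
    assert set(narrow) <= set(wide)
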