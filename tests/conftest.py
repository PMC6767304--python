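import numpy as np
import pytest

from dmcminer.constants import MASS_TABLE, PROTON_MASS
from dmcminer.formula import parse_formula
from dmcminer.spectra import load_packaged_fixtures


@pytest.fixture(scope="session")
def htf():
    """The prototype drug: a hydroxylated tetramethoxyflavone, C19H18O7."""
    return parse_formula("C19H18O7")


@pytest.fixture(scope="session")
def fixtures_all():
    return load_packaged_fixtures((1, 2, 3))


@pytest.fixture(scope="session")
def table1(fixtures_all):
    return [r for r in fixtures_all if r.table == 1]


@pytest.fixture(scope="session")
def table2(fixtures_all):
    return [r for r in fixtures_all if r.table == 2]


@pytest.fixture(scope="session")
def table3(fixtures_all):
    return [r for r in fixtures_all if r.table == 3]


@pytest.fixture(scope="session")
def decomposition_grid():
    """Exhaustive candidate grid for the brute-force decomposition oracle.

    Every (C, H, O, S, N) combination inside the default constraint
    ranges, with neutral mass and RDB precomputed as flat arrays.
    """
    c = np.arange(0, 31)
    h = np.arange(0, 51)
    o = np.arange(0, 21)
    s = np.arange(0, 3)
    n = np.arange(0, 4)
    C, H, O, S, N = np.meshgrid(c, h, o, s, n, indexing="ij")
    C, H, O, S, N = (x.ravel() for x in (C, H, O, S, N))
    mass = (
        C * MASS_TABLE["C"]
        + H * MASS_TABLE["H"]
        + O * MASS_TABLE["O"]
        + S * MASS_TABLE["S"]
        + N * MASS_TABLE["N"]
    )
    rdb = C - H / 2 + N / 2 + 1
    nonzero = (C + H + O + S + N) > 0
    return {"C": C, "H": H, "O": O, "S": S, "N": N, "mass": mass,
            "rdb": rdb, "nonzero": nonzero}


def brute_force_decompose(grid, target_mz, mode="pos", tol_ppm=5.0):
    """Independent oracle: full-grid formula decomposition of an ion m/z."""
    if mode == "pos":
        theo = grid["mass"] + PROTON_MASS
    else:
        theo = grid["mass"] - PROTON_MASS
    ok = (
        grid["nonzero"]
        & (theo > 0)
        & (np.abs((target_mz - theo) / theo * 1e6) <= tol_ppm)
        & (grid["rdb"] >= 0)
        & (grid["rdb"] <= 15)
    )
    out = set()
    for i in np.nonzero(ok)[0]:
        counts = {
            el: int(grid[el][i])
            for el in ("C", "H", "O", "S", "N")
            if grid[el][i] > 0
        }
        out.add(tuple(sorted(counts.items())))
    return out
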