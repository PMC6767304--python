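"""Physical constants and the packaged monoisotopic mass table."""

from __future__ import annotations

from importlib import resources

#: Mass of the proton, Da.
PROTON_MASS = 1.0072764666
#: Mass of the electron, Da.
ELECTRON_MASS = 0.0005485799
#: Mass of the neutral hydrogen atom, Da (proton + electron to <1e-6 Da).
H_ATOM_MASS = PROTON_MASS + ELECTRON_MASS


def load_mass_table() -> dict[str, float]:
    """Read the packaged element -> monoisotopic mass (Da) table."""
    text = (
        resources.files("dmcminer").joinpath("data/atomic_masses.tsv").read_text()
    )
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbol, mass = line.split("\t")
        table[symbol] = float(mass)
    return table


#: Module-level mass table shared by all formula arithmetic.
MASS_TABLE: dict[str, float] = load_mass_table()
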