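"""Readers and writers for centroided LC-MS^n data and fixture tables.

Supported formats:

* mzML (read) and MGF (read/write) through :mod:`pyteomics`;
* an internal tab-separated run dialect (read/write) used by the
  synthetic generator — one scan per line, peaks as ``mz:intensity``
  pairs, floats serialised with ``repr`` so round trips are bit exact;
* the fixture-table TSV dialect transcribing published identification
  tables, including the ``MSn[prec]:mz(int),...`` fragment-string
  mini-language (superscript markers such as ``MS^2^`` are tolerated).

MS^n spectra are assembled into precursor-linked trees
(:class:`MSnTree`): an MS^2 scan hangs off the MS^1 feature that
triggered it, an MS^3 scan off the MS^2 peak it re-isolated.  Fragment
m/z values from ion-trap stages are nominal, so tree linking uses a
±0.5 Th window while MS^1 matching elsewhere is ppm-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .formula import ChemicalFormula, parse_formula

__all__ = [
    "Polarity",
    "Peak",
    "SpectrumRecord",
    "MSnTree",
    "FixtureRecord",
    "SpectrumFormatError",
    "MsnStringError",
    "read_run",
    "write_run",
    "parse_msn_string",
    "load_fixtures",
    "fixture_table_path",
    "build_msn_trees",
]


class SpectrumFormatError(ValueError):
    """Unreadable, empty, or profile-mode spectral data."""


class MsnStringError(ValueError):
    """A fragment string that does not match the MSn mini-language."""


class Polarity(str, Enum):
    pos = "pos"
    neg = "neg"


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass
class SpectrumRecord:
    """One centroided scan.  Peaks are kept sorted by m/z."""

    ms_level: int
    polarity: Polarity
    retention_time: float  # minutes
    peaks: list[Peak]
    precursor_mz: float | None = None
    scan_id: str = ""

    def __post_init__(self) -> None:
        if self.ms_level >= 2 and self.precursor_mz is None:
            raise ValueError("MS^n scans (n >= 2) require a precursor m/z")
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    def base_peak(self) -> Peak | None:
        return max(self.peaks, key=lambda p: p.intensity, default=None)

    def total_intensity(self) -> float:
        return sum(p.intensity for p in self.peaks)


@dataclass
class MSnTree:
    """A precursor-linked MS^2 -> MS^3 -> ... spectral tree.

    The root spectrum is an MS^2 scan; children are deeper stages keyed
    by the parent peak they re-isolated (within the linking tolerance).
    """

    spectrum: SpectrumRecord
    children: list["MSnTree"] = field(default_factory=list)

    @property
    def precursor_mz(self) -> float:
        assert self.spectrum.precursor_mz is not None
        return self.spectrum.precursor_mz

    @property
    def polarity(self) -> Polarity:
        return self.spectrum.polarity

    def all_spectra(self) -> list[SpectrumRecord]:
        out = [self.spectrum]
        for c in self.children:
            out.extend(c.all_spectra())
        return out

    def all_peaks(self) -> list[tuple[int, Peak]]:
        """(ms_level, peak) pairs over the whole tree."""
        out = [(self.spectrum.ms_level, p) for p in self.spectrum.peaks]
        for c in self.children:
            out.extend(c.all_peaks())
        return out


# ---------------------------------------------------------------------------
# Run I/O
# ---------------------------------------------------------------------------

_RUN_HEADER = "scan_id\tms_level\tpolarity\trt_min\tprecursor_mz\tpeaks"


def _read_run_tsv(path: str | Path) -> list[SpectrumRecord]:
    records: list[SpectrumRecord] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines or lines[0] != _RUN_HEADER:
        raise SpectrumFormatError(f"{path}: not an internal run TSV (bad header)")
    for ln in lines[1:]:
        scan_id, level, pol, rt, prec, peaks = ln.split("\t")
        peak_list = []
        if peaks:
            for tok in peaks.split(","):
                mz, inten = tok.split(":")
                peak_list.append(Peak(float(mz), float(inten)))
        records.append(
            SpectrumRecord(
                ms_level=int(level),
                polarity=Polarity(pol),
                retention_time=float(rt),
                peaks=peak_list,
                precursor_mz=float(prec) if prec else None,
                scan_id=scan_id,
            )
        )
    return records


def _write_run_tsv(records: Sequence[SpectrumRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_RUN_HEADER + "\n")
        for r in records:
            peaks = ",".join(f"{repr(p.mz)}:{repr(p.intensity)}" for p in r.peaks)
            prec = repr(r.precursor_mz) if r.precursor_mz is not None else ""
            fh.write(
                f"{r.scan_id}\t{r.ms_level}\t{r.polarity.value}\t"
                f"{repr(r.retention_time)}\t{prec}\t{peaks}\n"
            )


def _read_run_mzml(path: str | Path) -> list[SpectrumRecord]:
    from pyteomics import mzml as _mzml

    records: list[SpectrumRecord] = []
    with _mzml.MzML(str(path)) as reader:
        for spec in reader:
            if "profile spectrum" in spec:
                raise SpectrumFormatError(
                    f"{path}: profile-mode data is unsupported; centroid first"
                )
            polarity = (
                Polarity.neg if "negative scan" in spec else Polarity.pos
            )
            level = int(spec.get("ms level", 1))
            rt = None
            for scan in spec.get("scanList", {}).get("scan", []):
                if "scan start time" in scan:
                    rt = float(scan["scan start time"])
            prec = None
            if level >= 2:
                precs = spec.get("precursorList", {}).get("precursor", [])
                ions = precs[0]["selectedIonList"]["selectedIon"] if precs else []
                if ions:
                    prec = float(ions[0]["selected ion m/z"])
            peaks = [
                Peak(float(mz), float(inten))
                for mz, inten in zip(spec["m/z array"], spec["intensity array"])
            ]
            records.append(
                SpectrumRecord(
                    ms_level=level,
                    polarity=polarity,
                    retention_time=rt if rt is not None else 0.0,
                    peaks=peaks,
                    precursor_mz=prec,
                    scan_id=str(spec.get("id", "")),
                )
            )
    if not records:
        raise SpectrumFormatError(f"{path}: no spectra found")
    return records


def _read_run_mgf(path: str | Path) -> list[SpectrumRecord]:
    from pyteomics import mgf as _mgf

    records: list[SpectrumRecord] = []
    with _mgf.MGF(str(path)) as reader:
        for spec in reader:
            params = spec["params"]
            prec = float(params["pepmass"][0]) if "pepmass" in params else None
            charge = params.get("charge")
            polarity = Polarity.pos
            if charge and str(charge[0]).endswith("-"):
                polarity = Polarity.neg
            rt = float(params.get("rtinseconds", 0.0)) / 60.0
            level = int(params.get("mslevel", 2))
            peaks = [
                Peak(float(mz), float(inten))
                for mz, inten in zip(spec["m/z array"], spec["intensity array"])
            ]
            records.append(
                SpectrumRecord(
                    ms_level=level,
                    polarity=polarity,
                    retention_time=rt,
                    peaks=peaks,
                    precursor_mz=prec,
                    scan_id=str(params.get("title", "")),
                )
            )
    if not records:
        raise SpectrumFormatError(f"{path}: no spectra found")
    return records


def read_run(path: str | Path, fmt: str | None = None) -> list[SpectrumRecord]:
    """Read a centroided run (mzML, MGF, or the internal TSV dialect).

    The format is inferred from the file extension unless ``fmt`` is
    given.  Scans are returned in acquisition order.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise SpectrumFormatError(f"{path}: missing or empty file")
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "mzml":
        return _read_run_mzml(path)
    if fmt == "mgf":
        return _read_run_mgf(path)
    if fmt in ("tsv", "txt", "run"):
        return _read_run_tsv(path)
    raise SpectrumFormatError(f"{path}: unknown run format {fmt!r}")


def write_run(
    records: Sequence[SpectrumRecord], path: str | Path, fmt: str | None = None
) -> None:
    """Write a run as internal TSV or MGF (MS^n scans only for MGF)."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt in ("tsv", "txt", "run"):
        _write_run_tsv(records, path)
        return
    if fmt == "mgf":
        from pyteomics import mgf as _mgf

        entries = []
        for r in records:
            if r.ms_level < 2:
                continue
            entries.append(
                {
                    "m/z array": [p.mz for p in r.peaks],
                    "intensity array": [p.intensity for p in r.peaks],
                    "params": {
                        "title": r.scan_id,
                        "pepmass": r.precursor_mz,
                        "rtinseconds": r.retention_time * 60.0,
                        "charge": "1+" if r.polarity is Polarity.pos else "1-",
                    },
                }
            )
        _mgf.write(entries, str(path), file_mode="w")
        return
    raise SpectrumFormatError(f"cannot write format {fmt!r}")


# ---------------------------------------------------------------------------
# The MSn fragment-string mini-language
# ---------------------------------------------------------------------------


def parse_msn_string(text: str) -> tuple[int, int, list[tuple[float, float]]]:
    """Parse ``MSn[prec]:mz(int),...`` into (level, precursor, peaks).

    Tolerates superscript markers (``MS^2^``), internal whitespace and a
    trailing comma; relative intensities must lie in (0, 100].  Raises
    :class:`MsnStringError` naming the offending position otherwise.
    """
    s = text.replace("^", "").replace(" ", "").strip()
    if not s.startswith("MS"):
        raise MsnStringError(f"{text!r}: must start with 'MS'")
    i = 2
    j = i
    while j < len(s) and s[j].isdigit():
        j += 1
    if j == i:
        raise MsnStringError(f"{text!r}: missing MS level at position {i}")
    level = int(s[i:j])
    if j >= len(s) or s[j] != "[":
        raise MsnStringError(f"{text!r}: expected '[' at position {j}")
    k = s.find("]", j)
    if k < 0:
        raise MsnStringError(f"{text!r}: unterminated precursor bracket")
    try:
        precursor = int(s[j + 1 : k])
    except ValueError as exc:
        raise MsnStringError(f"{text!r}: bad precursor {s[j+1:k]!r}") from exc
    if k + 1 >= len(s) or s[k + 1] != ":":
        raise MsnStringError(f"{text!r}: expected ':' after precursor")
    body = s[k + 2 :].rstrip(",")
    peaks: list[tuple[float, float]] = []
    if body:
        for tok in body.split(","):
            if not tok.endswith(")") or "(" not in tok:
                raise MsnStringError(f"{text!r}: malformed peak token {tok!r}")
            mz_s, int_s = tok[:-1].split("(", 1)
            try:
                mz, rel = float(mz_s), float(int_s)
            except ValueError as exc:
                raise MsnStringError(f"{text!r}: bad number in {tok!r}") from exc
            if not (0 < rel <= 100):
                raise MsnStringError(
                    f"{text!r}: relative intensity {rel} outside (0, 100]"
                )
            peaks.append((mz, rel))
    return level, precursor, peaks


def msn_string_to_spectrum(
    text: str, polarity: Polarity, retention_time: float = 0.0
) -> SpectrumRecord:
    """Materialise a fragment string as a :class:`SpectrumRecord`."""
    level, precursor, peaks = parse_msn_string(text)
    return SpectrumRecord(
        ms_level=level,
        polarity=polarity,
        retention_time=retention_time,
        peaks=[Peak(mz, rel) for mz, rel in peaks],
        precursor_mz=float(precursor),
    )


# ---------------------------------------------------------------------------
# Fixture tables
# ---------------------------------------------------------------------------


@dataclass
class FixtureRecord:
    """One transcribed row of a published identification table."""

    table: int
    label: str
    ion_mode: Polarity
    rt_min: float | None
    ion_formula_text: str
    ion_formula: ChemicalFormula | None
    theoretical_mz: float | None
    experimental_mz: float | None
    error_ppm: float | None
    msn_strings: tuple[str, ...]
    reaction: str
    note: str
    status: str  # "identified" for tables 1/2, "potential" for table 3

    def msn_tree(self) -> MSnTree | None:
        """Assemble the row's fragment strings into one spectral tree."""
        if not self.msn_strings:
            return None
        spectra = [
            msn_string_to_spectrum(s, self.ion_mode, self.rt_min or 0.0)
            for s in self.msn_strings
        ]
        spectra.sort(key=lambda s: s.ms_level)
        root = MSnTree(spectra[0])
        nodes = {spectra[0].ms_level: root}
        for spec in spectra[1:]:
            parent = nodes.get(spec.ms_level - 1, root)
            child = MSnTree(spec)
            parent.children.append(child)
            nodes[spec.ms_level] = child
        return root


def fixture_table_path(table: int) -> Path:
    """Path of a packaged fixture table (1-4)."""
    res = resources.files("dmcminer").joinpath(f"data/tables/table{table}.tsv")
    return Path(str(res))


def load_fixtures(path: str | Path) -> list[FixtureRecord]:
    """Load one fixture TSV; rejects rows violating invariants by number."""
    records: list[FixtureRecord] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    header: list[str] | None = None
    for lineno, ln in enumerate(lines, start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        if header is None:
            header = ln.split("\t")
            continue
        fields = ln.split("\t")
        fields += [""] * (len(header) - len(fields))
        row = dict(zip(header, fields))
        try:
            table = int(row["table"])
            theo = float(row["theoretical_mz"]) if row["theoretical_mz"] else None
            exp = float(row["experimental_mz"]) if row["experimental_mz"] else None
            if (theo is not None and theo <= 0) or (exp is not None and exp <= 0):
                raise ValueError("non-positive m/z")
            formula_text = row["ion_formula"]
            formula = parse_formula(formula_text) if formula_text else None
            msn = tuple(s for s in row["msn"].split("|") if s)
            if table == 3 and msn:
                raise ValueError("table-3 rows must not carry fragment strings")
            records.append(
                FixtureRecord(
                    table=table,
                    label=row["label"],
                    ion_mode=Polarity.pos if row["ion_mode"] == "P" else Polarity.neg,
                    rt_min=float(row["rt_min"]) if row["rt_min"] else None,
                    ion_formula_text=formula_text,
                    ion_formula=formula,
                    theoretical_mz=theo,
                    experimental_mz=exp,
                    error_ppm=float(row["error_ppm"]) if row["error_ppm"] else None,
                    msn_strings=msn,
                    reaction=row.get("reaction", ""),
                    note=row.get("note", ""),
                    status="potential" if table == 3 else "identified",
                )
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}: bad fixture row at line {lineno}: {exc}") from exc
    return records


def load_packaged_fixtures(tables: Iterable[int] = (1, 2, 3)) -> list[FixtureRecord]:
    """Load the packaged transcriptions of the published tables."""
    out: list[FixtureRecord] = []
    for t in tables:
        out.extend(load_fixtures(fixture_table_path(t)))
    return out


# ---------------------------------------------------------------------------
# Tree assembly from runs
# ---------------------------------------------------------------------------


def build_msn_trees(
    run: Sequence[SpectrumRecord], link_tolerance: float = 0.5
) -> list[MSnTree]:
    """Link MS^n scans of a run into precursor-resolved trees.

    An MS^2 scan roots a tree; each deeper scan attaches to the most
    recent shallower scan whose peak list contains its precursor within
    ``link_tolerance`` Th.  Orphan deep scans root their own tree.
    """
    trees: list[MSnTree] = []
    open_nodes: dict[int, MSnTree] = {}  # ms_level -> last node at that level
    for spec in run:
        if spec.ms_level < 2:
            open_nodes.clear()
            continue
        node = MSnTree(spec)
        parent = open_nodes.get(spec.ms_level - 1)
        attached = False
        if parent is not None and spec.precursor_mz is not None:
            if any(
                abs(p.mz - spec.precursor_mz) <= link_tolerance
                for p in parent.spectrum.peaks
            ):
                parent.children.append(node)
                attached = True
        if not attached:
            trees.append(node)
        open_nodes[spec.ms_level] = node
        # deeper stale nodes no longer apply
        for lvl in list(open_nodes):
            if lvl > spec.ms_level:
                del open_nodes[lvl]
    return trees
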