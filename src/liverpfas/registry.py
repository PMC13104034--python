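"""Chemistry registry for the targeted PFAS panel.

Holds the analyte descriptions the rest of the pipeline keys on: elemental
formula, chemical class, perfluorinated-carbon count, linear/branched isomer
label, and the extractable internal standard (EIS) assigned to each analyte
for isotope-dilution quantification.  Fluorine mass fractions computed here
drive the conversion of targeted concentrations to fluorine equivalents in
the organofluorine mass balance.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "Analyte",
    "Panel",
    "parse_formula",
    "format_formula",
    "molecular_weight",
    "fluorine_mass_fraction",
    "default_panel",
    "CHEM_CLASSES",
    "ATOMIC_MASSES",
]

# IUPAC 2021 standard atomic weights, abridged to 3 decimals.  The panel only
# needs CHNOF S Cl, but a few extras cost nothing.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Br": 79.904,
    "I": 126.904,
}

CHEM_CLASSES = (
    "PFCA",
    "PFSA",
    "FTCA",
    "FTS",
    "FOSAA_sulfonamide",
    "chlorinated_ether",
    "PFECA",
    "cyclic_PFSA",
)

ISOMERS = ("linear", "branched", "total")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class RegistryError(ValueError):
    """Invalid analyte/panel configuration."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation molecular formula, e.g. ``"C8HF15O2"``.

    Returns an element -> count mapping.  Repeated element symbols are
    accumulated.  Raises :class:`RegistryError` for unknown element symbols
    or syntactically invalid input.
    """
    if not formula or not isinstance(formula, str):
        raise RegistryError(f"empty or non-string formula: {formula!r}")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise RegistryError(f"cannot parse formula {formula!r} at position {pos}")
        if not m.group(0):
            break
        pos = m.end()
        elem = m.group(1)
        if elem not in ATOMIC_MASSES:
            raise RegistryError(f"unknown element symbol {elem!r} in formula {formula!r}")
        counts[elem] = counts.get(elem, 0) + (int(m.group(2)) if m.group(2) else 1)
    if pos != len(formula):
        raise RegistryError(f"cannot parse formula {formula!r} at position {pos}")
    if not counts:
        raise RegistryError(f"empty formula {formula!r}")
    return counts


def format_formula(counts: dict[str, int]) -> str:
    """Render an element-count map in Hill order (C, H, then alphabetical)."""
    elems = sorted(counts, key=lambda e: (e != "C", e != "H", e))
    return "".join(f"{e}{counts[e] if counts[e] != 1 else ''}" for e in elems if counts[e])


@dataclass(frozen=True)
class Analyte:
    """One targeted PFAS.

    Parameters
    ----------
    name:
        Identifier as reported, e.g. ``"L-PFOS"`` (linear) / ``"Br-PFOS"``
        (branched).  Unique within a panel.
    chem_class:
        One of :data:`CHEM_CLASSES`.
    formula:
        Element -> count map of the neutral acid (anion masses differ by one
        H; see :meth:`molecular_weight`).
    n_pfc:
        Number of perfluorinated carbons (chain-length metric).
    isomer:
        ``"linear"``, ``"branched"`` or ``"total"``.
    eis_name:
        Name of the mass-labeled extractable internal standard spiked before
        extraction and used as the quantification surrogate.
    eis_same_structure:
        Whether the EIS is the labeled analogue of this exact analyte
        (retention-time acceptance window 0.1 min) or a structurally
        different surrogate (0.4 min window with CCV shift correction).
    """

    name: str
    chem_class: str
    formula: dict[str, int] = field(hash=False)
    n_pfc: int
    isomer: str
    eis_name: str
    eis_same_structure: bool = True

    def __post_init__(self) -> None:
        if self.chem_class not in CHEM_CLASSES:
            raise RegistryError(f"{self.name}: unknown chemical class {self.chem_class!r}")
        if self.isomer not in ISOMERS:
            raise RegistryError(f"{self.name}: unknown isomer label {self.isomer!r}")
        if self.formula.get("F", 0) < 1:
            raise RegistryError(f"{self.name}: formula contains no fluorine; not a PFAS")
        n_c = self.formula.get("C", 0)
        if not (1 <= self.n_pfc <= n_c):
            raise RegistryError(
                f"{self.name}: n_pfc={self.n_pfc} outside [1, carbon count={n_c}]"
            )
        if not self.eis_name:
            raise RegistryError(f"{self.name}: missing EIS assignment")


def molecular_weight(analyte: Analyte | dict[str, int] | str, *, anion: bool = False) -> float:
    """Molecular weight in g/mol from the elemental formula.

    ``anion=True`` removes one H (the acids in the panel are all monoprotic),
    giving the deprotonated mass.  Default is the neutral acid.
    """
    if isinstance(analyte, Analyte):
        counts = analyte.formula
    elif isinstance(analyte, str):
        counts = parse_formula(analyte)
    else:
        counts = analyte
    if not counts:
        raise RegistryError("empty formula")
    mw = 0.0
    for elem, n in counts.items():
        try:
            mw += ATOMIC_MASSES[elem] * n
        except KeyError:
            raise RegistryError(f"unknown element symbol {elem!r}") from None
    if anion:
        if counts.get("H", 0) < 1:
            raise RegistryError("cannot deprotonate a formula with no hydrogen")
        mw -= ATOMIC_MASSES["H"]
    return mw


def fluorine_mass_fraction(analyte: Analyte | dict[str, int] | str, *, anion: bool = False) -> float:
    """Mass fraction of fluorine, in (0, 1].

    Used to convert a targeted concentration (ng analyte / g) into a fluorine
    equivalent (ng F / g) for comparison against extractable organofluorine.
    """
    if isinstance(analyte, Analyte):
        counts = analyte.formula
    elif isinstance(analyte, str):
        counts = parse_formula(analyte)
    else:
        counts = analyte
    n_f = counts.get("F", 0)
    if n_f < 1:
        raise RegistryError("formula contains no fluorine; not a PFAS")
    return n_f * ATOMIC_MASSES["F"] / molecular_weight(counts, anion=anion)


@dataclass
class Panel:
    """Ordered analyte panel plus the internal-standard inventory."""

    analytes: list[Analyte]
    eis_list: list[str] = field(default_factory=list)
    nis_list: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a.name for a in self.analytes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise RegistryError(f"duplicate analyte names in panel: {sorted(dupes)}")
        if not self.eis_list:
            self.eis_list = sorted({a.eis_name for a in self.analytes})
        missing = {a.eis_name for a in self.analytes} - set(self.eis_list)
        if missing:
            raise RegistryError(f"EIS assignments not in panel EIS list: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.analytes)

    def __iter__(self):
        return iter(self.analytes)

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.analytes]

    def get(self, name: str) -> Analyte:
        for a in self.analytes:
            if a.name == name:
                return a
        raise KeyError(f"analyte {name!r} not in panel")

    def classes(self) -> dict[str, list[str]]:
        """Map chemical class -> analyte names, covering the whole panel."""
        out: dict[str, list[str]] = {}
        for a in self.analytes:
            out.setdefault(a.chem_class, []).append(a.name)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [a.name for a in self.analytes],
                "chem_class": [a.chem_class for a in self.analytes],
                "formula": [format_formula(a.formula) for a in self.analytes],
                "n_pfc": [a.n_pfc for a in self.analytes],
                "isomer": [a.isomer for a in self.analytes],
                "eis_name": [a.eis_name for a in self.analytes],
                "eis_same_structure": [a.eis_same_structure for a in self.analytes],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Panel":
        required = {"name", "chem_class", "formula", "n_pfc", "isomer", "eis_name"}
        missing = required - set(df.columns)
        if missing:
            raise RegistryError(f"panel table missing columns: {sorted(missing)}")
        analytes = [
            Analyte(
                name=str(r["name"]),
                chem_class=str(r["chem_class"]),
                formula=parse_formula(str(r["formula"])),
                n_pfc=int(r["n_pfc"]),
                isomer=str(r["isomer"]),
                eis_name=str(r["eis_name"]),
                eis_same_structure=bool(r.get("eis_same_structure", True)),
            )
            for _, r in df.iterrows()
        ]
        return cls(analytes=analytes)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Panel":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def from_json(cls, path: str | Path) -> "Panel":
        with open(path) as fh:
            return cls.from_frame(pd.DataFrame(json.load(fh)))


# Default panel: the analytes reported by name in the study, with neutral-acid
# formulas.  (name, class, formula, n_pfc, isomer, EIS, same-structure EIS).
# Branched and linear isomers are distinct entries sharing one formula.
_DEFAULT_PANEL_ROWS: list[tuple[str, str, str, int, str, str, bool]] = [
    # perfluoroalkyl carboxylic acids
    ("PFBA",       "PFCA", "C4HF7O2",    3,  "total",    "13C4-PFBA",    True),
    ("PFHxA",      "PFCA", "C6HF11O2",   5,  "total",    "13C5-PFHxA",   True),
    ("PFHpA",      "PFCA", "C7HF13O2",   6,  "total",    "13C4-PFHpA",   True),
    ("PFOA",       "PFCA", "C8HF15O2",   7,  "linear",   "13C8-PFOA",    True),
    ("PFNA",       "PFCA", "C9HF17O2",   8,  "linear",   "13C9-PFNA",    True),
    ("PFDA",       "PFCA", "C10HF19O2",  9,  "linear",   "13C6-PFDA",    True),
    ("PFUdA",      "PFCA", "C11HF21O2",  11, "linear",   "13C7-PFUdA",   True),
    ("PFDoA",      "PFCA", "C12HF23O2",  12, "linear",   "13C2-PFDoA",   True),
    ("PFTrDA",     "PFCA", "C13HF25O2",  13, "linear",   "13C2-PFDoA",   False),
    ("PFTeDA",     "PFCA", "C14HF27O2",  14, "linear",   "13C2-PFTeDA",  True),
    # perfluoroalkyl sulfonic acids
    ("L-PFHxS",    "PFSA", "C6HF13O3S",  6,  "linear",   "13C3-PFHxS",   True),
    ("Br-PFHxS",   "PFSA", "C6HF13O3S",  6,  "branched", "13C3-PFHxS",   False),
    ("PFHpS",      "PFSA", "C7HF15O3S",  7,  "total",    "13C3-PFHxS",   False),
    ("L-PFOS",     "PFSA", "C8HF17O3S",  8,  "linear",   "13C8-PFOS",    True),
    ("Br-PFOS",    "PFSA", "C8HF17O3S",  8,  "branched", "13C8-PFOS",    False),
    ("PFDS",       "PFSA", "C10HF21O3S", 10, "total",    "13C8-PFOS",    False),
    # perfluorooctanesulfonamides and derivatives
    ("FOSA",         "FOSAA_sulfonamide", "C8H2F17NO2S",  8, "total",    "13C8-FOSA",      True),
    ("L-N-MeFOSAA",  "FOSAA_sulfonamide", "C11H6F17NO4S", 8, "linear",   "d3-N-MeFOSAA",   True),
    ("Br-N-MeFOSAA", "FOSAA_sulfonamide", "C11H6F17NO4S", 8, "branched", "d3-N-MeFOSAA",   False),
    ("L-N-EtFOSAA",  "FOSAA_sulfonamide", "C12H8F17NO4S", 8, "linear",   "d5-N-EtFOSAA",   True),
    # fluorotelomer sulfonic acids
    ("4:2 FTS",    "FTS",  "C6H5F9O3S",  4,  "total",    "13C2-6:2 FTS", False),
    ("6:2 FTS",    "FTS",  "C8H5F13O3S", 6,  "total",    "13C2-6:2 FTS", True),
    ("8:2 FTS",    "FTS",  "C10H5F17O3S", 8, "total",    "13C2-8:2 FTS", True),
    ("10:2 FTS",   "FTS",  "C12H5F21O3S", 10, "total",   "13C2-8:2 FTS", False),
    # fluorotelomer carboxylic acids
    ("3:3 FTCA",   "FTCA", "C6H5F7O2",   3,  "total",    "13C2-PFHxA",   False),
    ("5:3 FTCA",   "FTCA", "C8H5F11O2",  5,  "total",    "13C4-PFHpA",   False),
    ("7:3 FTCA",   "FTCA", "C10H5F15O2", 7,  "total",    "13C9-PFNA",    False),
    # chlorinated polyfluoroalkyl ether sulfonic acids (F-53B components)
    ("9Cl-PF3ONS",   "chlorinated_ether", "C8HClF16O4S",  8,  "total", "13C8-PFOS", False),
    ("11Cl-PF3OUdS", "chlorinated_ether", "C10HClF20O4S", 10, "total", "13C8-PFOS", False),
    # perfluoroalkyl ether carboxylic acids
    ("3,6-OPFHpA", "PFECA", "C5HF9O4",   3,  "total",    "13C3-HFPO-DA", False),
    # cyclic perfluoroalkyl sulfonic acids
    ("PFECHS",     "cyclic_PFSA", "C8HF15O3S", 8, "total", "13C8-PFOS",  False),
]

_DEFAULT_NIS = ["13C2-PFOA(NIS)", "13C4-PFOS(NIS)"]


def default_panel() -> Panel:
    """The built-in panel of targeted analytes reported in U.S. liver tissue.

    A real deployment supplies the laboratory's full target list (the method
    this emulates quantifies 54); this default covers the compounds detected
    and discussed by name, spanning all eight chemical classes, and is the
    panel the synthetic generator simulates.
    """
    analytes = [
        Analyte(
            name=n, chem_class=c, formula=parse_formula(f), n_pfc=npfc,
            isomer=iso, eis_name=eis, eis_same_structure=same,
        )
        for (n, c, f, npfc, iso, eis, same) in _DEFAULT_PANEL_ROWS
    ]
    return Panel(analytes=analytes, nis_list=list(_DEFAULT_NIS))
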