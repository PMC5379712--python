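"""Theoretical b/y fragment-ion computation and spectrum annotation for
modified peptides (e.g. the CENP-A tryptic peptide VTLFPKDVQLAR carrying
K124 acetylation or monomethylation at its sixth residue).

Masses are monoisotopic throughout: b_i is the sum of the first i residue
masses (with their modifications) plus a proton; y_i the sum of the last i
residue masses plus water plus a proton; an ion of charge z has
m/z = (neutral_fragment + z * proton) / z.  Neutral losses and a/c/z series
are intentionally not produced (CID b/y only).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .model import ModelError

__all__ = [
    "PROTON",
    "WATER",
    "RESIDUE_MASSES",
    "MODIFICATIONS",
    "Peptide",
    "IonEntry",
    "peptide_mass",
    "ion_series",
    "precursor_mz",
    "annotate_spectrum",
    "render_ion_table",
]

PROTON = 1.007276
WATER = 18.010565

#: Monoisotopic residue (amino-acid minus water) masses, Da.
RESIDUE_MASSES = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

#: Monoisotopic mass deltas (Da) of supported modifications.
MODIFICATIONS = {
    "acetyl": 42.010565,
    "methyl": 14.015650,
    "dimethyl": 28.031300,
    "trimethyl": 42.046950,
    "phospho": 79.966331,
    "gg": 114.042927,  # ubiquitin remnant
}


@dataclass(frozen=True)
class Peptide:
    """A peptide with 1-based position -> modification-name mapping."""

    sequence: str
    mods: dict[int, str] = field(default_factory=dict)
    n_term_delta: float = 0.0
    c_term_delta: float = 0.0

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ModelError("empty peptide sequence")
        for aa in seq:
            if aa not in RESIDUE_MASSES:
                raise ModelError(f"unknown residue {aa!r}")
        for pos, name in self.mods.items():
            if not 1 <= pos <= len(seq):
                raise ModelError(f"modification position {pos} outside peptide")
            if name not in MODIFICATIONS:
                raise ModelError(f"unknown modification {name!r}")
        object.__setattr__(self, "mods", dict(self.mods))

    def __len__(self) -> int:
        return len(self.sequence)

    def residue_masses(self) -> list[float]:
        """Per-residue masses including modification deltas."""

        masses = [RESIDUE_MASSES[aa] for aa in self.sequence]
        for pos, name in self.mods.items():
            masses[pos - 1] += MODIFICATIONS[name]
        return masses

    def without_mod(self, position: int) -> "Peptide":
        mods = {p: m for p, m in self.mods.items() if p != position}
        return replace(self, mods=mods)


@dataclass
class IonEntry:
    series: str  # 'b' or 'y'
    index: int
    charge: int
    theoretical_mz: float
    matched_mz: float | None = None
    delta: float | None = None  # matched - theoretical, Da
    ambiguous: bool = False

    @property
    def label(self) -> str:
        sup = "+" * self.charge
        return f"{self.series}{self.index}{sup}"


def peptide_mass(p: Peptide) -> float:
    """Monoisotopic neutral mass: residues + water + terminal deltas, Da."""

    return sum(p.residue_masses()) + WATER + p.n_term_delta + p.c_term_delta


def precursor_mz(p: Peptide, z: int) -> float:
    """m/z of the [M + zH]^z+ precursor."""

    if z < 1:
        raise ModelError("charge must be >= 1")
    return (peptide_mass(p) + z * PROTON) / z


def ion_series(p: Peptide, charges: set[int] | tuple[int, ...] = (1,)) -> list[IonEntry]:
    """All b_i / y_i ions (i = 1..len-1) at the requested charges."""

    charges = sorted(set(int(z) for z in charges))
    if any(z < 1 for z in charges):
        raise ModelError("charges must be >= 1")
    masses = p.residue_masses()
    n = len(masses)
    entries: list[IonEntry] = []
    prefix = 0.0
    b_neutral = []
    for m in masses[:-1]:
        prefix += m
        b_neutral.append(prefix + p.n_term_delta)
    suffix = 0.0
    y_neutral = []
    for m in reversed(masses[1:]):
        suffix += m
        y_neutral.append(suffix + WATER + p.c_term_delta)
    for series, neutrals in (("b", b_neutral), ("y", y_neutral)):
        for i, neutral in enumerate(neutrals, start=1):
            for z in charges:
                entries.append(
                    IonEntry(series, i, z, theoretical_mz=(neutral + z * PROTON) / z)
                )
    return entries


def annotate_spectrum(
    p: Peptide,
    peaks,
    tol: float = 0.4,
    charges: set[int] | tuple[int, ...] = (1, 2),
) -> list[IonEntry]:
    """Match theoretical ions to the nearest observed peak within ``tol`` Da.

    One peak may satisfy several theoretical ions; all such entries are
    flagged ambiguous.  Unmatched ions are kept with ``matched_mz=None``.
    """

    if tol <= 0:
        raise ModelError("tolerance must be > 0")
    peaks = sorted(float(x) for x in peaks)
    entries = ion_series(p, charges)
    assignments: dict[int, list[int]] = {}
    for k, e in enumerate(entries):
        if not peaks:
            continue
        best = min(range(len(peaks)), key=lambda i: abs(peaks[i] - e.theoretical_mz))
        if abs(peaks[best] - e.theoretical_mz) <= tol:
            e.matched_mz = peaks[best]
            e.delta = peaks[best] - e.theoretical_mz
            assignments.setdefault(best, []).append(k)
    for ks in assignments.values():
        if len(ks) > 1:
            for k in ks:
                entries[k].ambiguous = True
    return entries


_MOD_LABELS = {
    "acetyl": "Acetyl",
    "methyl": "Methyl",
    "dimethyl": "Dimethyl",
    "trimethyl": "Trimethyl",
    "phospho": "Phospho",
    "gg": "GG",
}


def render_ion_table(p: Peptide, charges: tuple[int, ...] = (1, 2)) -> pd.DataFrame:
    """Tabular b/y ladder: one row per residue, b ascending, y descending.

    Rows are labeled like published fragment tables: residue i carries b_i
    (absent on the last row) and y_{n-i+1} (absent on the first row, which
    would be the intact peptide); modified residues are labeled
    'K-Acetyl' / 'K-Methyl' style.
    """

    charges = tuple(sorted(set(charges)))
    ions = {(e.series, e.index, e.charge): e.theoretical_mz for e in ion_series(p, charges)}
    n = len(p)
    rows = []
    for i in range(1, n + 1):
        aa = p.sequence[i - 1]
        label = aa
        if i in p.mods:
            label = f"{aa}-{_MOD_LABELS[p.mods[i]]}"
        row: dict[str, object] = {"#": i}
        for z in charges:
            key = "b+" if z == 1 else f"b{z}+"
            row[key] = round(ions[("b", i, z)], 5) if i < n else None
        row["Seq."] = label
        yi = n - i + 1
        for z in charges:
            key = "y+" if z == 1 else f"y{z}+"
            row[key] = round(ions[("y", yi, z)], 5) if yi < n else None
        row["#(y)"] = yi
        rows.append(row)
    return pd.DataFrame(rows)
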