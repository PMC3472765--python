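"""Exact mass arithmetic for residues, peptides, modifications and ions.

All residue masses are derived at import time from elemental compositions
and a single embedded atomic-mass table, so that identities such as

    gg_delta_mass("monoisotopic") == 2 * residue_mono["G"]

hold exactly (both sides are sums of the same atomic constants).
Internal arithmetic is full double precision; the conventional printed
figures are 2 d.p. for monoisotopic and 1 d.p. for average masses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

# Atomic masses: monoisotopic from the AME/IUPAC atomic-mass evaluation,
# average (standard atomic weight) from the IUPAC 2021 table; >=5 d.p.
ATOMIC_MONO: Dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}
ATOMIC_AVG: Dict[str, float] = {
    "H": 1.00794,
    "C": 12.0107,
    "N": 14.0067,
    "O": 15.9994,
    "S": 32.065,
}

#: CODATA proton mass in Da.
PROTON_MONO: float = 1.00727646688

# Residue (i.e. amino acid minus water) elemental compositions.
_RESIDUE_FORMULAS: Dict[str, Dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

_WATER = {"H": 2, "O": 1}

# The Gly-Gly remnant left on lysine after tryptic digestion of a
# ubiquitin conjugate: two glycine residues, both in amide linkage, so
# no extra water -- composition C4H6N2O2.
GG_COMPOSITION: Dict[str, int] = {"C": 4, "H": 6, "N": 2, "O": 2}

MASS_KINDS = ("monoisotopic", "average")


@dataclass(frozen=True)
class ElementalComposition:
    """An integer element-count vector over C, H, N, O, S."""

    counts: Dict[str, int]

    def __post_init__(self) -> None:
        for element, n in self.counts.items():
            if element not in ATOMIC_MONO:
                raise ValueError(f"unknown element {element!r}")
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"count for {element} must be a non-negative integer, got {n!r}")

    def mass(self, kind: str = "monoisotopic") -> float:
        table = _atomic_table(kind)
        return sum(n * table[el] for el, n in self.counts.items())


def _atomic_table(kind: str) -> Dict[str, float]:
    if kind == "monoisotopic":
        return ATOMIC_MONO
    if kind == "average":
        return ATOMIC_AVG
    raise ValueError(f"kind must be one of {MASS_KINDS}, got {kind!r}")


def _formula_mass(formula: Dict[str, int], kind: str) -> float:
    table = _atomic_table(kind)
    return sum(n * table[el] for el, n in formula.items())


@dataclass(frozen=True)
class ResidueMassTable:
    """Monoisotopic and average residue masses plus physical constants."""

    residue_mono: Dict[str, float] = field(
        default_factory=lambda: {
            aa: _formula_mass(f, "monoisotopic") for aa, f in _RESIDUE_FORMULAS.items()
        }
    )
    residue_avg: Dict[str, float] = field(
        default_factory=lambda: {
            aa: _formula_mass(f, "average") for aa, f in _RESIDUE_FORMULAS.items()
        }
    )
    water_mono: float = _formula_mass(_WATER, "monoisotopic")
    water_avg: float = _formula_mass(_WATER, "average")
    proton_mono: float = PROTON_MONO

    def residue(self, aa: str, kind: str = "monoisotopic") -> float:
        table = self.residue_mono if kind == "monoisotopic" else self.residue_avg
        if kind not in MASS_KINDS:
            raise ValueError(f"kind must be one of {MASS_KINDS}, got {kind!r}")
        try:
            return table[aa]
        except KeyError:
            raise KeyError(f"unknown residue code {aa!r}") from None

    def water(self, kind: str = "monoisotopic") -> float:
        return self.water_mono if kind == "monoisotopic" else self.water_avg


#: Module-level default table; all masses in the package flow through it.
MASSES = ResidueMassTable()

# Modification deltas, monoisotopic Da.
GG_DELTA_MONO: float = _formula_mass(GG_COMPOSITION, "monoisotopic")
#: Fixed cysteine carbamidomethylation (+C2H3NO).
CARBAMIDOMETHYL_DELTA: float = _formula_mass({"C": 2, "H": 3, "N": 1, "O": 1}, "monoisotopic")
#: Variable methionine oxidation (+O).
OXIDATION_DELTA: float = _formula_mass({"O": 1}, "monoisotopic")

GG_LABEL = "GG"


def gg_delta_mass(kind: str = "monoisotopic") -> float:
    """Mass added to a lysine by an isopeptide-linked Gly-Gly remnant.

    Both glycines are in amide linkage so the delta is exactly two glycine
    residue masses (C4H6N2O2): 114.04 Da monoisotopic, 114.1 Da average.
    """
    return ElementalComposition(GG_COMPOSITION).mass(kind)


def peptide_mass(peptide, kind: str = "monoisotopic") -> float:
    """Neutral mass of a (possibly modified) peptide.

    ``peptide`` may be a plain sequence string or any object with
    ``sequence`` and ``mods`` attributes (``mods`` being an iterable of
    ``(position, delta, label)`` tuples).  Mass = sum of residue masses +
    one water + sum of modification deltas.
    """
    if isinstance(peptide, str):
        sequence: str = peptide
        mods: Sequence[Tuple[int, float, str]] = ()
    else:
        sequence = peptide.sequence
        mods = peptide.mods
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    total = MASSES.water(kind)
    for aa in sequence:
        try:
            total += MASSES.residue(aa, kind)
        except KeyError:
            raise ValueError(f"unknown residue code {aa!r} in {sequence!r}") from None
    total += sum(delta for _, delta, _ in mods)
    return total


def mz(mass: float, charge: int) -> float:
    """m/z of an ion of the given neutral mass carrying ``charge`` protons."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (mass + charge * PROTON_MONO) / charge


def neutral_mass(mz_value: float, charge: int) -> float:
    """Inverse of :func:`mz`: deconvolute an observed m/z to neutral mass."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz_value * charge - charge * PROTON_MONO
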