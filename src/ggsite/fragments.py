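"""Theoretical b/y fragment ions for GG-branched peptides.

A "branched" fragment is any b- or y-ion whose residue span includes a
GG-modified lysine; its m/z is shifted by +114.04293/z relative to the
unbranched homolog.  The remnant itself is treated as an inert mass on
the lysine -- fragmentation within the Gly-Gly branch is not modelled.
Neutral-loss and a-ions are deliberately out of scope: the acceptance
rule counts branched b/y evidence only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence

from ggsite.digestion import ModifiedPeptide
from ggsite.masscore import MASSES, PROTON_MONO, peptide_mass


@dataclass(frozen=True)
class TheoreticalFragment:
    series: str  # 'b' or 'y'
    index: int  # 1..len(peptide)-1
    charge: int
    mz: float
    branched: bool


def generate_fragments(
    peptide: ModifiedPeptide,
    fragment_charges: Iterable[int] = (1, 2),
) -> List[TheoreticalFragment]:
    """Full b1..b(n-1) and y1..y(n-1) ladders at each requested charge.

    b-ion neutral mass = sum of N-terminal residues (+ mods in span);
    y-ion neutral mass = sum of C-terminal residues (+ mods in span) +
    water.  The branched flag marks fragments whose span covers at least
    one GG-modified lysine.
    """
    seq = peptide.sequence
    n = len(seq)
    if n < 2:
        raise ValueError("peptide must have length >= 2 to fragment")
    charges = sorted(set(fragment_charges))
    if any(z < 1 for z in charges):
        raise ValueError("fragment charges must be positive")

    # Prefix sums of residue + modification masses, index 0..n.
    prefix = [0.0]
    mod_delta = [0.0] * (n + 1)
    for pos, delta, _ in peptide.mods:
        mod_delta[pos] += delta
    for i, aa in enumerate(seq, start=1):
        prefix.append(prefix[-1] + MASSES.residue(aa) + mod_delta[i])
    gg = set(peptide.gg_positions)
    water = MASSES.water_mono

    fragments: List[TheoreticalFragment] = []
    for i in range(1, n):
        b_neutral = prefix[i]
        y_neutral = prefix[n] - prefix[n - i] + water
        b_branched = any(p <= i for p in gg)
        y_branched = any(p > n - i for p in gg)
        for z in charges:
            fragments.append(
                TheoreticalFragment("b", i, z, (b_neutral + z * PROTON_MONO) / z, b_branched)
            )
            fragments.append(
                TheoreticalFragment("y", i, z, (y_neutral + z * PROTON_MONO) / z, y_branched)
            )
    fragments.sort(key=lambda f: (f.charge, f.series, f.index))
    return fragments


def complementary_check(
    fragments: Sequence[TheoreticalFragment],
    peptide_mass_da: float,
    tol: float = 1e-4,
) -> bool:
    """Internal consistency oracle for singly-charged ladders.

    True iff mz(b_i, 1) + mz(y_{n-i}, 1) == peptide mass + 2*proton for
    every index i.  Raises if the singly-charged ladders are incomplete.
    """
    b = {f.index: f.mz for f in fragments if f.series == "b" and f.charge == 1}
    y = {f.index: f.mz for f in fragments if f.series == "y" and f.charge == 1}
    if not b or set(b) != set(y) or set(b) != set(range(1, max(b) + 1)):
        raise ValueError("complementary_check requires complete singly-charged b/y ladders")
    n = max(b) + 1
    expected = peptide_mass_da + 2 * PROTON_MONO
    return all(abs(b[i] + y[n - i] - expected) <= tol for i in range(1, n))
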