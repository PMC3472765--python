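"""In-silico trypsin digestion with missed cleavages and GG-blocked lysines.

Trypsin cuts after K or R except before P.  A lysine carrying the Gly-Gly
remnant is refractory to cleavage, so its junction is removed from the set
of cleavage sites altogether: it is neither cut nor counted against the
missed-cleavage budget.  That exemption keeps long signature peptides
spanning a modified K reachable under the usual two-missed-cleavage limit.

Coordinates are 1-based and inclusive throughout ("K442"-style site
labels).  No N-terminal methionine stripping is performed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, Set, Tuple

from ggsite.masscore import GG_DELTA_MONO, GG_LABEL, mz, peptide_mass

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")

Mod = Tuple[int, float, str]  # (1-based position in peptide, delta Da, label)


@dataclass(frozen=True)
class ProteinSequence:
    """A protein with optional planted GG sites (1-based lysine positions)."""

    accession: str
    sequence: str
    planted_sites: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_AA
        if bad:
            raise ValueError(
                f"{self.accession}: non-amino-acid characters {sorted(bad)!r} in sequence"
            )
        for pos in self.planted_sites:
            if not (1 <= pos <= len(self.sequence)) or self.sequence[pos - 1] != "K":
                raise ValueError(
                    f"{self.accession}: planted site {pos} does not index a lysine"
                )
        object.__setattr__(self, "planted_sites", tuple(sorted(self.planted_sites)))

    @property
    def lysine_positions(self) -> Tuple[int, ...]:
        return tuple(i + 1 for i, aa in enumerate(self.sequence) if aa == "K")


@dataclass(frozen=True)
class ModifiedPeptide:
    """A digestion product, possibly carrying GG (or other) modifications.

    ``start`` is the peptide's 1-based position in the parent protein;
    ``mods`` holds ``(position-in-peptide, delta, label)`` triples with
    1-based positions.
    """

    sequence: str
    start: int = 1
    mods: Tuple[Mod, ...] = ()
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        for pos, _, label in self.mods:
            if not (1 <= pos <= len(self.sequence)):
                raise ValueError(f"modification position {pos} outside peptide")
            if label == GG_LABEL and self.sequence[pos - 1] != "K":
                raise ValueError(f"GG modification at position {pos} is not on a lysine")
        object.__setattr__(self, "mods", tuple(sorted(self.mods)))

    @property
    def end(self) -> int:
        """1-based inclusive end position in the parent protein."""
        return self.start + len(self.sequence) - 1

    @property
    def gg_positions(self) -> Tuple[int, ...]:
        """1-based positions (within the peptide) of GG-modified lysines."""
        return tuple(pos for pos, _, label in self.mods if label == GG_LABEL)

    def gg_protein_positions(self) -> Tuple[int, ...]:
        return tuple(self.start + p - 1 for p in self.gg_positions)


def _cleavage_sites(sequence: str, blocked: Set[int]) -> List[int]:
    """0-based indices i such that trypsin cuts between sequence[i] and [i+1].

    ``blocked`` holds 1-based positions of GG-modified lysines, which are
    removed from the site list entirely.
    """
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and sequence[i + 1] != "P" and (i + 1) not in blocked:
            sites.append(i)
    return sites


def digest(
    protein: ProteinSequence,
    max_missed: int = 2,
    enzyme: str = "trypsin",
) -> List[ModifiedPeptide]:
    """Enumerate tryptic peptides with 0..max_missed missed cleavages.

    GG-modified lysines (``protein.planted_sites``) block cleavage and do
    not consume the missed-cleavage budget; emitted peptides carry the GG
    modifications they cover.  Concatenating the 0-missed-cleavage
    peptides in order reconstructs the protein.
    """
    if enzyme != "trypsin":
        raise ValueError(f"unsupported enzyme {enzyme!r}")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = protein.sequence
    blocked = set(protein.planted_sites)
    sites = _cleavage_sites(seq, blocked)
    # Segment boundaries: [start, end) in 0-based coordinates.
    starts = [0] + [i + 1 for i in sites]
    ends = [i + 1 for i in sites] + [len(seq)]
    n_seg = len(starts)
    peptides: List[ModifiedPeptide] = []
    for i in range(n_seg):
        for m in range(max_missed + 1):
            j = i + m
            if j >= n_seg:
                break
            start0, end0 = starts[i], ends[j]
            sub = seq[start0:end0]
            mods = tuple(
                (pos - start0, GG_DELTA_MONO, GG_LABEL)
                for pos in protein.planted_sites
                if start0 < pos <= end0
            )
            peptides.append(
                ModifiedPeptide(sequence=sub, start=start0 + 1, mods=mods, missed_cleavages=m)
            )
    return peptides


def enumerate_signature_candidates(
    protein: ProteinSequence,
    max_missed: int = 2,
    charges: Iterable[int] = (2, 3, 4),
) -> List[Tuple[ModifiedPeptide, int, float]]:
    """Candidate (GG peptide, precursor charge, precursor m/z) triples.

    When ``protein.planted_sites`` is non-empty the enumeration is
    restricted to those lysines (targeted mode); otherwise every lysine in
    the protein is considered in turn (discovery mode).  Each target site
    is hypothesised independently -- candidate peptides carry exactly one
    GG, which blocks only its own cleavage junction -- so adding a target
    site never removes candidates for the others.  Only peptides long
    enough to fragment are candidates.
    """
    charges = sorted(set(charges))
    if any(z < 1 for z in charges):
        raise ValueError("charges must be positive")
    targets = protein.planted_sites or protein.lysine_positions
    out: List[Tuple[ModifiedPeptide, int, float]] = []
    seen = set()
    for site in targets:
        prot = ProteinSequence(protein.accession, protein.sequence, (site,))
        for pep in digest(prot, max_missed=max_missed):
            if site not in pep.gg_protein_positions():
                continue
            if len(pep.sequence) < 2:  # cannot yield fragment ions
                continue
            # A GG-K at the peptide C-terminus can only occur at the
            # protein C-terminus (cleavage there is blocked otherwise).
            key = (pep.sequence, pep.start, pep.mods)
            if key in seen:
                continue
            seen.add(key)
            mass = peptide_mass(pep)
            for z in charges:
                out.append((pep, z, mz(mass, z)))
    out.sort(key=lambda c: (c[0].start, c[0].end, c[0].mods, c[1]))
    return out


def read_fasta(path) -> List[ProteinSequence]:
    """Read protein sequences from a FASTA file (plain or gzip).

    The accession is the first whitespace-delimited token of the header.
    """
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        return [
            ProteinSequence(record.id, str(record.seq).upper())
            for record in SeqIO.parse(handle, "fasta")
        ]


def write_fasta(proteins: Sequence[ProteinSequence], path) -> None:
    with open(path, "w") as handle:
        for prot in proteins:
            handle.write(f">{prot.accession}\n")
            seq = prot.sequence
            for i in range(0, len(seq), 60):
                handle.write(seq[i : i + 60] + "\n")
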