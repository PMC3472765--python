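"""Synthetic proteomes and simulated MS1/MS2 data with planted GG sites.

The generator emulates the data-generating process the targeted search
assumes: random proteins with a vertebrate amino-acid background, GG
sites planted uniformly over lysines, Gaussian elution profiles in MS1
at the precursor m/z of every candidate GG peptide (charges 2+-4+), and
one MS2 spectrum near each elution apex containing the b/y ladders with
the +114.04-Da shift on branched ions, subject to per-ion dropout,
Gaussian m/z jitter, log-normal intensities and uniform noise peaks.
Unmodified tryptic peptides contribute distractor spectra.

It does not model isotope envelopes, chromatographic drift, co-isolation
or chemical noise, so a clean pass here shows the search logic is sound,
not that real ion-trap data would behave as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from ggsite.digestion import ModifiedPeptide, ProteinSequence, digest, enumerate_signature_candidates
from ggsite.fragments import generate_fragments
from ggsite.masscore import mz as compute_mz, peptide_mass
from ggsite.signature_search import SiteCall
from ggsite.spectra_io import Ms1Trace, Ms2Spectrum

# Swiss-Prot average amino-acid frequencies (percent), a standard
# vertebrate-like background giving ~5.8% lysine density.
AA_FREQUENCIES: Dict[str, float] = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.72, "G": 7.07, "H": 2.27, "I": 5.91,
    "L": 9.65, "K": 5.80, "M": 2.41, "F": 3.86, "P": 4.74,
    "S": 6.63, "T": 5.35, "W": 1.10, "Y": 2.92, "V": 6.86,
}


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the simulator; defaults describe a small clean run.

    ``elution_sigma`` is the Gaussian chromatographic peak width in
    seconds; ``fragment_dropout_prob`` is the per-theoretical-ion
    probability that an ion is absent from its MS2 spectrum;
    ``mass_jitter_sd`` (Da) is applied to every generated peak m/z;
    ``intensity_lognorm`` are the (mu, sigma) of log-intensities.
    """

    n_proteins: int = 20
    protein_length_range: Tuple[int, int] = (200, 400)
    n_planted_sites: int = 10
    elution_sigma: float = 5.0
    fragment_dropout_prob: float = 0.1
    noise_peaks_per_spectrum: int = 20
    noise_mz_range: Tuple[float, float] = (200.0, 1800.0)
    intensity_lognorm: Tuple[float, float] = (9.0, 0.6)
    mass_jitter_sd: float = 0.02
    seed: int = 1
    precursor_charges: Tuple[int, ...] = (2, 3, 4)
    fragment_charges: Tuple[int, ...] = (1, 2)
    max_missed: int = 2
    run_length: float = 3600.0  # a 60-min LC gradient
    scan_interval: float = 2.0
    distractors_per_protein: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.fragment_dropout_prob <= 1.0:
            raise ValueError("fragment_dropout_prob must lie in [0, 1]")
        for name in ("protein_length_range", "noise_mz_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered (min, max)")


@dataclass
class GroundTruth:
    """Planted sites and per-spectrum provenance."""

    sites: List[Tuple[str, int]] = field(default_factory=list)
    provenance: Dict[str, str] = field(default_factory=dict)


def simulate_proteome(config: SimConfig) -> Tuple[List[ProteinSequence], GroundTruth]:
    """Random proteins with GG sites planted uniformly over lysines.

    Residues are i.i.d. from :data:`AA_FREQUENCIES`; the requested number
    of sites is drawn without replacement from all lysine positions in
    the proteome.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    letters = np.array(list(AA_FREQUENCIES))
    probs = np.array(list(AA_FREQUENCIES.values()))
    probs = probs / probs.sum()
    lo, hi = config.protein_length_range
    sequences = []
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        sequences.append("".join(rng.choice(letters, size=length, p=probs)))
    lysines = [
        (i, pos + 1)
        for i, seq in enumerate(sequences)
        for pos, aa in enumerate(seq)
        if aa == "K"
    ]
    if config.n_planted_sites > len(lysines):
        raise ValueError(
            f"cannot plant {config.n_planted_sites} sites: only {len(lysines)} lysines generated"
        )
    chosen_idx = rng.choice(len(lysines), size=config.n_planted_sites, replace=False)
    planted: Dict[int, List[int]] = {}
    for idx in sorted(int(j) for j in chosen_idx):
        prot_i, pos = lysines[idx]
        planted.setdefault(prot_i, []).append(pos)
    proteins = []
    truth = GroundTruth()
    for i, seq in enumerate(sequences):
        acc = f"SYN{i:04d}"
        sites = tuple(planted.get(i, ()))
        proteins.append(ProteinSequence(acc, seq, sites))
        truth.sites.extend((acc, pos) for pos in sites)
    return proteins, truth


def _lognormal(rng: np.random.Generator, mu: float, sigma: float, size=None):
    return np.exp(rng.normal(mu, sigma, size=size))


def simulate_spectra(
    proteins: Sequence[ProteinSequence],
    truth: GroundTruth,
    config: SimConfig,
) -> Tuple[Ms1Trace, List[Ms2Spectrum]]:
    """Simulated MS1 trace and MS2 spectra for a planted proteome.

    Every candidate GG peptide (each covering peptide x each precursor
    charge) receives a Gaussian elution profile in MS1 and one MS2
    spectrum near its apex; distractor MS2 spectra come from unmodified
    tryptic peptides.  Provenance for each spectrum id is recorded in
    ``truth.provenance``.
    """
    rng = np.random.default_rng(config.seed + 1)
    mu, sigma = config.intensity_lognorm

    # --- candidate GG peptides with elution profiles
    elutions = []  # (precursor_mz, apex_rt, amplitude, peptide, charge, accession)
    for prot in proteins:
        if not prot.planted_sites:
            continue
        for pep, z, pmz in enumerate_signature_candidates(
            prot, max_missed=config.max_missed, charges=config.precursor_charges
        ):
            apex = float(rng.uniform(0.1 * config.run_length, 0.9 * config.run_length))
            amp = float(_lognormal(rng, mu + 2.0, sigma))
            elutions.append((pmz, apex, amp, pep, z, prot.accession))

    # --- MS1 trace: Gaussian profiles sampled on a regular scan grid
    scan_rts = np.arange(0.0, config.run_length + 1e-9, config.scan_interval)
    scans = []
    for rt in scan_rts:
        mzs, ints = [], []
        for pmz, apex, amp, _, _, _ in elutions:
            if abs(rt - apex) > 4.0 * config.elution_sigma:
                continue
            intensity = amp * np.exp(-0.5 * ((rt - apex) / config.elution_sigma) ** 2)
            mzs.append(pmz + rng.normal(0.0, config.mass_jitter_sd))
            ints.append(intensity)
        order = np.argsort(mzs)
        scans.append(
            (float(rt), np.asarray(mzs, dtype=float)[order], np.asarray(ints, dtype=float)[order])
        )
    trace = Ms1Trace(scans)

    # --- MS2 spectra for candidates
    spectra: List[Ms2Spectrum] = []
    for k, (pmz, apex, amp, pep, z, acc) in enumerate(elutions):
        sid = f"sim{k:05d}"
        mzs, ints = [], []
        for frag in generate_fragments(pep, config.fragment_charges):
            if rng.random() < config.fragment_dropout_prob:
                continue
            mzs.append(frag.mz + rng.normal(0.0, config.mass_jitter_sd))
            ints.append(float(_lognormal(rng, mu, sigma)))
        n_noise = config.noise_peaks_per_spectrum
        if n_noise:
            lo, hi = config.noise_mz_range
            mzs.extend(rng.uniform(lo, hi, size=n_noise).tolist())
            ints.extend(_lognormal(rng, mu, sigma, size=n_noise).tolist())
        rt = apex + float(rng.normal(0.0, 2.0))
        spectra.append(
            Ms2Spectrum(
                spectrum_id=sid,
                precursor_mz=pmz + float(rng.normal(0.0, config.mass_jitter_sd)),
                precursor_charge=z,
                retention_time=rt,
                mz=np.asarray(mzs),
                intensity=np.asarray(ints),
            )
        )
        sites = ",".join(f"K{p}" for p in pep.gg_protein_positions())
        truth.provenance[sid] = f"{acc}:{pep.start}-{pep.end}/{z}+ {sites}"

    # --- distractor spectra from unmodified peptides
    counter = len(elutions)
    for prot in proteins:
        bare = ProteinSequence(prot.accession, prot.sequence)
        peps = [p for p in digest(bare, max_missed=0) if 6 <= len(p.sequence) <= 25]
        if not peps:
            continue
        take = min(config.distractors_per_protein, len(peps))
        for idx in rng.choice(len(peps), size=take, replace=False):
            pep = peps[int(idx)]
            sid = f"sim{counter:05d}"
            counter += 1
            mzs, ints = [], []
            for frag in generate_fragments(pep, config.fragment_charges):
                if rng.random() < config.fragment_dropout_prob:
                    continue
                mzs.append(frag.mz + rng.normal(0.0, config.mass_jitter_sd))
                ints.append(float(_lognormal(rng, mu, sigma)))
            if config.noise_peaks_per_spectrum:
                lo, hi = config.noise_mz_range
                mzs.extend(rng.uniform(lo, hi, size=config.noise_peaks_per_spectrum).tolist())
                ints.extend(
                    _lognormal(rng, mu, sigma, size=config.noise_peaks_per_spectrum).tolist()
                )
            spectra.append(
                Ms2Spectrum(
                    spectrum_id=sid,
                    precursor_mz=compute_mz(peptide_mass(pep), 2)
                    + float(rng.normal(0.0, config.mass_jitter_sd)),
                    precursor_charge=2,
                    retention_time=float(rng.uniform(0.0, config.run_length)),
                    mz=np.asarray(mzs),
                    intensity=np.asarray(ints),
                )
            )
            truth.provenance[sid] = "noise"
    return trace, spectra


class Recovery(NamedTuple):
    recall: float
    precision: float
    precision_defined: bool = True


def score_recovery(calls: Sequence[SiteCall], truth: GroundTruth) -> Recovery:
    """Site-level recall/precision of accepted calls against the truth.

    Matching is exact on (accession, position).  With no accepted calls,
    precision is undefined and reported as 1.0 with
    ``precision_defined=False``.
    """
    found = {(c.accession, c.site_position) for c in calls if c.accepted}
    true = set(truth.sites)
    recall = len(found & true) / len(true) if true else 1.0
    if not found:
        return Recovery(recall, 1.0, precision_defined=False)
    return Recovery(recall, len(found & true) / len(found))
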