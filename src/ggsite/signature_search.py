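"""Targeted GG-signature search.

The search proceeds in three stages, mirroring a targeted
LC-MS/MS workflow on an ion trap:

1. **XIC screening** -- every candidate GG peptide (from
   :func:`ggsite.digestion.enumerate_signature_candidates`, precursor
   charges 2+..4+) is screened by narrow-window (default +/- 0.3 m/z)
   extracted ion chromatography against the MS1 trace; candidates with no
   signal are dropped and the elution apex is recorded for MS2 pairing.
2. **Branched fragment matching** -- MS2 spectra acquired near the apex
   and at the candidate's precursor m/z are matched against the
   theoretical b/y ladders.  Matching is a greedy nearest-first
   one-to-one assignment of theoretical ions to peaks within the
   fragment tolerance.  A site is accepted only when at least
   ``min_branched_ions`` (default 4) matched fragments are branched,
   i.e. carry the GG remnant.
3. **Protein-level filtering** -- accepted evidence is rolled up per
   accession under a two-peptide rule: at least two distinct peptides
   with score >= 7 and a summed protein score >= 14.

The peptide score is a transparent surrogate for a proprietary search
engine score: 10 x (matched / theoretical ions) + 2 x branched matches.
It is monotone in evidence and calibrated so the 7/14 thresholds are
attainable by clean ladders and unreachable by chance matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from ggsite.digestion import (
    ModifiedPeptide,
    ProteinSequence,
    enumerate_signature_candidates,
)
from ggsite.fragments import TheoreticalFragment, generate_fragments
from ggsite.masscore import neutral_mass, peptide_mass
from ggsite.spectra_io import Ms1Trace, Ms2Spectrum


@dataclass(frozen=True)
class SearchConfig:
    """Tolerances and thresholds of the targeted search.

    Defaults follow the ion-trap settings the pipeline was designed
    around: 1.6 Da precursor window (monoisotopic, Da not ppm), 0.5 Da
    MS/MS tolerance, +/-0.3 m/z XIC window, >=4 branched ions per site,
    two peptides of score >=7 summing to >=14 per protein, two missed
    cleavages, precursor charges 2+-4+.
    """

    precursor_tol: float = 1.6
    fragment_tol: float = 0.5
    xic_halfwidth: float = 0.3
    min_branched_ions: int = 4
    precursor_charges: Tuple[int, ...] = (2, 3, 4)
    max_missed: int = 2
    min_peptides_per_protein: int = 2
    min_peptide_score: float = 7.0
    min_protein_score: float = 14.0
    min_scored_intensity_fraction: float = 0.7
    fragment_charges: Tuple[int, ...] = (1, 2)
    xic_min_intensity: float = 0.0
    rt_window: float = 30.0
    use_xic: bool = True

    def __post_init__(self) -> None:
        for name in ("precursor_tol", "fragment_tol", "xic_halfwidth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_branched_ions < 1:
            raise ValueError("min_branched_ions must be >= 1")


@dataclass(frozen=True)
class SiteCall:
    """One candidate ubiquitination site and its fragment-ion evidence."""

    accession: str
    site_position: int
    peptide: ModifiedPeptide
    charge: int
    n_branched_matched: int
    n_total_matched: int
    peptide_score: float
    accepted: bool
    spectrum_id: str = ""
    ambiguous: bool = False
    scored_intensity_fraction: float = 0.0


@dataclass(frozen=True)
class ProteinCall:
    accession: str
    site_calls: Tuple[SiteCall, ...]
    distinct_peptides: int
    protein_score: float
    accepted: bool


@dataclass(frozen=True)
class ScreenedCandidate:
    peptide: ModifiedPeptide
    accession: str
    charge: int
    precursor_mz: float
    apex_rt: Optional[float] = None


# ---------------------------------------------------------------------------
# XIC screening


def extract_xic(
    trace: Ms1Trace, target_mz: float, halfwidth: float = 0.3
) -> List[Tuple[float, float]]:
    """Narrow-window extracted ion chromatogram.

    For each MS1 scan, sums the intensities of peaks with
    ``|mz - target_mz| <= halfwidth``; returns one (retention time,
    summed intensity) point per scan.  An empty trace yields an empty XIC.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be > 0")
    xic = []
    for rt, mz_arr, int_arr in trace.scans:
        mask = np.abs(mz_arr - target_mz) <= halfwidth
        xic.append((rt, float(int_arr[mask].sum())))
    return xic


def screen_candidates(
    trace: Ms1Trace,
    candidates: Sequence[ScreenedCandidate],
    config: SearchConfig,
) -> List[ScreenedCandidate]:
    """Retain candidates with detectable XIC signal; record the apex.

    Co-eluting candidates within one window are all retained -- there is
    no mutual exclusion at this stage.
    """
    if not trace.scans:
        return []
    # Flatten the trace once and index peaks by m/z; each candidate's XIC
    # is then a searchsorted slice + per-scan bincount, equivalent to
    # calling extract_xic per candidate but O(log N + hits).
    rts = trace.retention_times
    scan_idx = np.concatenate(
        [np.full(len(mz_arr), i) for i, (_, mz_arr, _) in enumerate(trace.scans)]
    )
    all_mz = np.concatenate([mz_arr for _, mz_arr, _ in trace.scans])
    all_int = np.concatenate([int_arr for _, _, int_arr in trace.scans])
    order = np.argsort(all_mz, kind="stable")
    all_mz, all_int, scan_idx = all_mz[order], all_int[order], scan_idx[order]

    out = []
    n_scans = len(trace.scans)
    for cand in candidates:
        lo = np.searchsorted(all_mz, cand.precursor_mz - config.xic_halfwidth, side="left")
        hi = np.searchsorted(all_mz, cand.precursor_mz + config.xic_halfwidth, side="right")
        if hi == lo:
            continue
        xic = np.bincount(scan_idx[lo:hi], weights=all_int[lo:hi], minlength=n_scans)
        peak = float(xic.max())
        if peak > config.xic_min_intensity:
            apex_rt = float(rts[int(np.argmax(xic))])
            out.append(replace(cand, apex_rt=apex_rt))
    return out


# ---------------------------------------------------------------------------
# Fragment matching


def _greedy_match(
    fragments: Sequence[TheoreticalFragment],
    peak_mz: np.ndarray,
    tol: float,
) -> Dict[int, int]:
    """Greedy one-to-one assignment of theoretical ions to peaks.

    Candidate pairs within ``tol`` are taken in order of ascending
    |delta m/z|, ties broken toward the lower-index fragment then the
    lower-m/z peak; each peak and each ion is used at most once.
    Returns {fragment list index -> peak index}.
    """
    pairs = []
    for fi, frag in enumerate(fragments):
        lo = np.searchsorted(peak_mz, frag.mz - tol, side="left")
        hi = np.searchsorted(peak_mz, frag.mz + tol, side="right")
        for pi in range(lo, hi):
            pairs.append((abs(peak_mz[pi] - frag.mz), fi, pi))
    pairs.sort()
    assignment: Dict[int, int] = {}
    used_peaks: set = set()
    for _, fi, pi in pairs:
        if fi in assignment or pi in used_peaks:
            continue
        assignment[fi] = pi
        used_peaks.add(pi)
    return assignment


def match_spectrum(
    spectrum: Ms2Spectrum,
    peptide: ModifiedPeptide,
    config: SearchConfig,
    accession: str = "",
) -> Optional[SiteCall]:
    """Match one spectrum against one candidate GG peptide.

    Returns ``None`` (candidate skipped) when the observed precursor
    neutral mass, after charge deconvolution, is outside
    ``precursor_tol`` of the theoretical peptide mass.  Matched
    fragments are counted as distinct species -- a (series, index) pair
    matched at both 1+ and 2+ is one fragment ion, not two.  A site is
    accepted when >= ``min_branched_ions`` distinct branched fragments
    matched AND the matched peaks carry at least
    ``min_scored_intensity_fraction`` of the spectrum's total intensity
    (a transparent rendition of the usual minimum-scored-peak-intensity
    identification criterion; it rejects candidates that leave the
    spectrum essentially unexplained).
    """
    theo_mass = peptide_mass(peptide)
    obs_mass = neutral_mass(spectrum.precursor_mz, spectrum.precursor_charge)
    if abs(obs_mass - theo_mass) > config.precursor_tol:
        return None
    fragments = generate_fragments(peptide, config.fragment_charges)
    assignment = _greedy_match(fragments, spectrum.mz, config.fragment_tol)
    matched_species = {(fragments[fi].series, fragments[fi].index) for fi in assignment}
    branched_species = {
        (fragments[fi].series, fragments[fi].index)
        for fi in assignment
        if fragments[fi].branched
    }
    n_total = len(matched_species)
    n_branched = len(branched_species)
    n_species = 2 * (len(peptide.sequence) - 1)
    total_intensity = float(spectrum.intensity.sum())
    if total_intensity > 0:
        matched_intensity = float(spectrum.intensity[sorted(assignment.values())].sum())
        explained = matched_intensity / total_intensity
    else:
        explained = 0.0
    score = 10.0 * n_total / n_species + 2.0 * n_branched
    sites = peptide.gg_protein_positions()
    return SiteCall(
        accession=accession,
        site_position=sites[0] if sites else 0,
        peptide=peptide,
        charge=spectrum.precursor_charge,
        n_branched_matched=n_branched,
        n_total_matched=n_total,
        peptide_score=score,
        accepted=(
            n_branched >= config.min_branched_ions
            and explained >= config.min_scored_intensity_fraction
        ),
        spectrum_id=spectrum.spectrum_id,
        scored_intensity_fraction=explained,
    )


# ---------------------------------------------------------------------------
# Protein-level filtering


def filter_proteins(
    site_calls: Sequence[SiteCall], config: SearchConfig
) -> List[ProteinCall]:
    """Two-peptide protein roll-up.

    Contributing peptides are distinct peptide species (sequence + mods)
    whose best score is >= ``min_peptide_score``; the protein score is
    the sum of contributing best scores.  A protein is accepted when it
    has >= ``min_peptides_per_protein`` contributing peptides and
    protein score >= ``min_protein_score``.
    """
    by_acc: Dict[str, List[SiteCall]] = {}
    for call in site_calls:
        by_acc.setdefault(call.accession, []).append(call)
    out = []
    for acc in sorted(by_acc):
        calls = by_acc[acc]
        best: Dict[Tuple, float] = {}
        for call in calls:
            key = (call.peptide.sequence, call.peptide.mods)
            best[key] = max(best.get(key, 0.0), call.peptide_score)
        contributing = {k: s for k, s in best.items() if s >= config.min_peptide_score}
        protein_score = sum(contributing.values())
        accepted = (
            len(contributing) >= config.min_peptides_per_protein
            and protein_score >= config.min_protein_score
        )
        out.append(
            ProteinCall(
                accession=acc,
                site_calls=tuple(
                    sorted(calls, key=lambda c: (c.site_position, c.charge, c.spectrum_id))
                ),
                distinct_peptides=len(contributing),
                protein_score=protein_score,
                accepted=accepted,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Pipeline


def _expand_site_calls(call: SiteCall) -> List[SiteCall]:
    """One call per GG site carried by the matched peptide."""
    sites = call.peptide.gg_protein_positions()
    return [replace(call, site_position=s) for s in sites]


def _resolve_ambiguity(calls: List[SiteCall]) -> List[SiteCall]:
    """Site-isoform resolution per spectrum.

    When one spectrum matched several isoforms of the same peptide
    (same sequence span, different GG position), only the isoform with
    the most matched branched ions is kept; exact ties are all kept but
    flagged ambiguous.
    """
    groups: Dict[Tuple, List[SiteCall]] = {}
    for call in calls:
        key = (call.spectrum_id, call.accession, call.peptide.sequence, call.peptide.start, call.charge)
        groups.setdefault(key, []).append(call)
    resolved: List[SiteCall] = []
    for group in groups.values():
        distinct_sites = {c.site_position for c in group}
        if len(distinct_sites) == 1:
            resolved.extend(group)
            continue
        top = max(c.n_branched_matched for c in group)
        winners = [c for c in group if c.n_branched_matched == top]
        if len({c.site_position for c in winners}) > 1:
            winners = [replace(c, ambiguous=True) for c in winners]
        resolved.extend(winners)
    return resolved


def run_search(
    proteins: Sequence[ProteinSequence],
    spectra: Sequence[Ms2Spectrum],
    trace: Optional[Ms1Trace] = None,
    config: SearchConfig = SearchConfig(),
) -> Tuple[List[SiteCall], List[ProteinCall]]:
    """Full pipeline: enumerate, screen, match, filter.

    With a trace and ``config.use_xic``, candidates are screened by XIC
    and spectra are paired to candidates by precursor m/z (within the XIC
    halfwidth) and retention time (within ``rt_window`` of the apex).
    Without a trace, pairing is by precursor m/z alone.  Returns
    deterministic, stably sorted site and protein calls.
    """
    candidates: List[ScreenedCandidate] = []
    for prot in proteins:
        for pep, z, pmz in enumerate_signature_candidates(
            prot, max_missed=config.max_missed, charges=config.precursor_charges
        ):
            candidates.append(ScreenedCandidate(pep, prot.accession, z, pmz))

    if trace is not None and config.use_xic:
        candidates = screen_candidates(trace, candidates, config)

    raw_calls: List[SiteCall] = []
    for spectrum in spectra:
        for cand in candidates:
            if cand.charge != spectrum.precursor_charge:
                continue
            if abs(spectrum.precursor_mz - cand.precursor_mz) > config.xic_halfwidth:
                continue
            if (
                cand.apex_rt is not None
                and abs(spectrum.retention_time - cand.apex_rt) > config.rt_window
            ):
                continue
            call = match_spectrum(spectrum, cand.peptide, config, accession=cand.accession)
            if call is None:
                continue
            raw_calls.extend(_expand_site_calls(call))

    calls = _resolve_ambiguity(raw_calls)
    calls.sort(
        key=lambda c: (c.accession, c.site_position, c.charge, c.spectrum_id, -c.peptide_score)
    )
    protein_calls = filter_proteins(calls, config)
    return calls, protein_calls
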