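"""XIC screening, branched-ion matching, acceptance rule, protein filter."""

from dataclasses import replace

import numpy as np
import pytest

from conftest import ladder_spectrum
from ggsite.digestion import ModifiedPeptide, ProteinSequence
from ggsite.fragments import generate_fragments
from ggsite.masscore import GG_DELTA_MONO, GG_LABEL, mz, peptide_mass
from ggsite.signature_search import (
    ScreenedCandidate,
    SearchConfig,
    SiteCall,
    _greedy_match,
    extract_xic,
    filter_proteins,
    match_spectrum,
    run_search,
    screen_candidates,
)
from ggsite.spectra_io import Ms1Trace
from ggsite.synthetic_data import SimConfig, score_recovery, simulate_proteome, simulate_spectra


def gg_peptide(seq, pos, start=1):
    return ModifiedPeptide(seq, start=start, mods=((pos, GG_DELTA_MONO, GG_LABEL),))


def scan(rt, peaks):
    mzs = np.array([m for m, _ in peaks])
    ints = np.array([i for _, i in peaks])
    order = np.argsort(mzs)
    return (rt, mzs[order], ints[order])


class TestXic:
    def test_single_peak_at_target(self):
        trace = Ms1Trace([scan(10.0, [(500.0, 123.0)])])
        assert extract_xic(trace, 500.0, 0.3) == [(10.0, 123.0)]

    def test_boundary_exclusion_just_outside_window(self):
        trace = Ms1Trace([scan(10.0, [(500.31, 99.0)])])
        assert extract_xic(trace, 500.0, 0.3) == [(10.0, 0.0)]

    def test_empty_trace_gives_empty_xic(self):
        assert extract_xic(Ms1Trace([]), 500.0, 0.3) == []

    def test_gaussian_apex_located(self):
        rts = np.arange(200.0, 400.0, 2.0)
        trace = Ms1Trace(
            [scan(rt, [(700.0, 1e4 * np.exp(-0.5 * ((rt - 300.0) / 5.0) ** 2))]) for rt in rts]
        )
        xic = extract_xic(trace, 700.0, 0.3)
        apex_rt = max(xic, key=lambda p: p[1])[0]
        assert abs(apex_rt - 300.0) <= 2.0


class TestScreening:
    def make_candidates(self):
        pep = gg_peptide("AGTKAGLR", 4)
        return [
            ScreenedCandidate(pep, "p", 2, 500.0),
            ScreenedCandidate(pep, "p", 2, 800.0),
            ScreenedCandidate(pep, "p", 2, 500.2),  # co-eluting within one window
        ]

    def test_zero_signal_dropped_others_kept_with_apex(self):
        trace = Ms1Trace(
            [scan(rt, [(500.0, 100.0 if rt == 40.0 else 10.0)]) for rt in (20.0, 40.0, 60.0)]
        )
        kept = screen_candidates(trace, self.make_candidates(), SearchConfig())
        assert [c.precursor_mz for c in kept] == [500.0, 500.2]
        assert all(c.apex_rt == 40.0 for c in kept)

    def test_screening_matches_reference_xic(self):
        rng = np.random.default_rng(5)
        trace = Ms1Trace(
            [scan(float(rt), [(float(m), float(i)) for m, i in
                              zip(rng.uniform(400, 900, 30), rng.uniform(1, 100, 30))])
             for rt in np.arange(0, 50, 2.0)]
        )
        cands = self.make_candidates()
        kept = screen_candidates(trace, cands, SearchConfig())
        for cand in cands:
            xic = extract_xic(trace, cand.precursor_mz, 0.3)
            expected_kept = max(v for _, v in xic) > 0
            assert (cand.precursor_mz in [c.precursor_mz for c in kept]) == expected_kept


class TestMatchSpectrum:
    config = SearchConfig()

    def test_noiseless_spectrum_accepted(self):
        pep = gg_peptide("SAMPLEKTIDER", 7)
        call = match_spectrum(ladder_spectrum(pep), pep, self.config, accession="p")
        assert call.accepted
        assert call.n_branched_matched >= 4
        assert call.scored_intensity_fraction == pytest.approx(1.0)
        assert call.site_position == 7

    def test_branched_peaks_deleted_rejected(self):
        pep = gg_peptide("SAMPLEKTIDER", 7)
        branched = {
            (f.series, f.index)
            for f in generate_fragments(pep, self.config.fragment_charges)
            if f.branched
        }
        spectrum = ladder_spectrum(pep, drop=branched)
        call = match_spectrum(spectrum, pep, self.config, accession="p")
        assert call.n_branched_matched == 0
        assert not call.accepted

    def test_exactly_three_branched_ions_rejected(self):
        # spectrum holds the full unbranched ladder plus exactly three
        # branched fragments; the >=4 rule alone must reject it
        pep = gg_peptide("SAMPLEKTIDER", 7)
        config = replace(self.config, fragment_charges=(1,), min_scored_intensity_fraction=0.0)
        frags = generate_fragments(pep, (1,))
        branched = sorted(
            ((f.series, f.index) for f in frags if f.branched)
        )
        spectrum = ladder_spectrum(pep, fragment_charges=(1,), drop=branched[3:])
        call = match_spectrum(spectrum, pep, config, accession="p")
        assert call.n_branched_matched == 3
        assert not call.accepted

    def test_four_branched_ions_accepted(self):
        pep = gg_peptide("SAMPLEKTIDER", 7)
        config = replace(self.config, fragment_charges=(1,), min_scored_intensity_fraction=0.0)
        frags = generate_fragments(pep, (1,))
        branched = sorted(((f.series, f.index) for f in frags if f.branched))
        spectrum = ladder_spectrum(pep, fragment_charges=(1,), drop=branched[4:])
        call = match_spectrum(spectrum, pep, config, accession="p")
        assert call.n_branched_matched == 4
        assert call.accepted

    def test_precursor_outside_tolerance_skipped(self):
        pep = gg_peptide("SAMPLEKTIDER", 7)
        spectrum = ladder_spectrum(pep)
        shifted = replace(spectrum, precursor_mz=spectrum.precursor_mz + 2.0)
        assert match_spectrum(shifted, pep, self.config) is None

    def test_unexplained_spectrum_rejected_despite_branched_matches(self):
        # four branched ions buried in a spectrum dominated by foreign peaks
        pep = gg_peptide("SAMPLEKTIDER", 7)
        frags = [f for f in generate_fragments(pep, (1,)) if f.branched][:4]
        extra = list(np.linspace(1550, 1950, 40))
        config = replace(self.config, fragment_charges=(1,))
        spectrum = ladder_spectrum(
            pep,
            fragment_charges=(1,),
            drop={(f.series, f.index) for f in generate_fragments(pep, (1,))}
            - {(f.series, f.index) for f in frags},
            extra_mz=extra,
        )
        call = match_spectrum(spectrum, pep, config)
        assert call.n_branched_matched >= 4
        assert not call.accepted

    def test_acceptance_monotone_in_min_branched_ions(self):
        pep = gg_peptide("SAMPLEKTIDER", 7)
        spectrum = ladder_spectrum(pep)
        accepted = []
        for k in range(1, 12):
            call = match_spectrum(
                spectrum, pep, replace(self.config, min_branched_ions=k)
            )
            accepted.append(call.accepted)
        # once rejected, stays rejected as the threshold rises
        assert accepted == sorted(accepted, reverse=True)

    def test_widening_fragment_tol_never_loses_matches(self):
        pep = gg_peptide("SAMPLEKTIDER", 7)
        rng = np.random.default_rng(7)
        spectrum = ladder_spectrum(pep, extra_mz=rng.uniform(100, 1500, 20))
        narrow = match_spectrum(spectrum, pep, replace(self.config, fragment_tol=0.1))
        wide = match_spectrum(spectrum, pep, replace(self.config, fragment_tol=0.5))
        assert wide.n_total_matched >= narrow.n_total_matched


class TestGreedyOracle:
    def test_matches_maximum_bipartite_matching_on_small_spectra(self):
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import maximum_bipartite_matching

        rng = np.random.default_rng(11)
        pep = gg_peptide("AGTKAGLR", 4)
        frags = generate_fragments(pep, (1,))
        for _ in range(50):
            n_peaks = rng.integers(1, 13)
            # peaks scattered near the theoretical ladder, one per ion
            base = rng.choice([f.mz for f in frags], size=n_peaks, replace=False)
            peaks = np.sort(base + rng.normal(0, 0.12, n_peaks))
            greedy = _greedy_match(frags, peaks, 0.5)
            rows, cols, data = [], [], []
            for fi, f in enumerate(frags):
                for pi, p in enumerate(peaks):
                    if abs(p - f.mz) <= 0.5:
                        rows.append(fi)
                        cols.append(pi)
                        data.append(1)
            biadj = csr_matrix(
                (data, (rows, cols)), shape=(len(frags), len(peaks))
            )
            optimal = (maximum_bipartite_matching(biadj, perm_type="column") >= 0).sum()
            assert len(greedy) == optimal


class TestFilterProteins:
    config = SearchConfig()

    def make_call(self, acc, seq, score):
        pep = ModifiedPeptide(seq)
        return SiteCall(
            accession=acc,
            site_position=1,
            peptide=pep,
            charge=2,
            n_branched_matched=4,
            n_total_matched=8,
            peptide_score=score,
            accepted=True,
        )

    def test_single_peptide_rejected(self):
        calls = [self.make_call("P1", "PEPTIDEK", 20.0)]
        (prot,) = filter_proteins(calls, self.config)
        assert not prot.accepted and prot.distinct_peptides == 1

    def test_boundary_two_sevens_accepted(self):
        calls = [
            self.make_call("P1", "PEPTIDEK", 7.0),
            self.make_call("P1", "SAMPLER", 7.0),
        ]
        (prot,) = filter_proteins(calls, self.config)
        assert prot.accepted
        assert prot.protein_score == pytest.approx(14.0)

    def test_subthreshold_peptide_does_not_contribute(self):
        calls = [
            self.make_call("P1", "PEPTIDEK", 7.0),
            self.make_call("P1", "SAMPLER", 7.0),
            self.make_call("P1", "TINYK", 2.0),
        ]
        (prot,) = filter_proteins(calls, self.config)
        assert prot.accepted and prot.distinct_peptides == 2
        assert prot.protein_score == pytest.approx(14.0)

    def test_duplicate_spectra_of_same_peptide_count_once(self):
        calls = [
            self.make_call("P1", "PEPTIDEK", 9.0),
            self.make_call("P1", "PEPTIDEK", 8.0),
        ]
        (prot,) = filter_proteins(calls, self.config)
        assert prot.distinct_peptides == 1 and prot.protein_score == pytest.approx(9.0)


class TestPipeline:
    def test_deterministic_and_recovers_planted_sites(self, clean_sim_config):
        proteins, truth = simulate_proteome(clean_sim_config)
        trace, spectra = simulate_spectra(proteins, truth, clean_sim_config)
        bare = [ProteinSequence(p.accession, p.sequence) for p in proteins]
        calls1, prots1 = run_search(bare, spectra, trace, SearchConfig())
        calls2, _ = run_search(bare, spectra, trace, SearchConfig())
        assert calls1 == calls2
        rec = score_recovery(calls1, truth)
        assert rec.recall == 1.0 and rec.precision == 1.0
        accepted_accs = {c.accession for c in calls1 if c.accepted}
        passing = {p.accession for p in prots1 if p.accepted}
        assert passing <= accepted_accs

    def test_raising_min_branched_never_increases_accepted_sites(self, clean_sim_config):
        cfg = replace(clean_sim_config, n_proteins=5, n_planted_sites=3)
        proteins, truth = simulate_proteome(cfg)
        trace, spectra = simulate_spectra(proteins, truth, cfg)
        bare = [ProteinSequence(p.accession, p.sequence) for p in proteins]
        counts = []
        for k in (2, 4, 8, 16, 32):
            calls, _ = run_search(
                bare, spectra, trace, SearchConfig(min_branched_ions=k)
            )
            counts.append(sum(1 for c in calls if c.accepted))
        assert counts == sorted(counts, reverse=True)

    def test_no_xic_mode_still_recovers(self, clean_sim_config):
        cfg = replace(clean_sim_config, n_proteins=5, n_planted_sites=3)
        proteins, truth = simulate_proteome(cfg)
        trace, spectra = simulate_spectra(proteins, truth, cfg)
        bare = [ProteinSequence(p.accession, p.sequence) for p in proteins]
        calls, _ = run_search(bare, spectra, None, SearchConfig(use_xic=False))
        assert score_recovery(calls, truth).recall == 1.0
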