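# Methods

## The signature model

Ubiquitination leaves, after trypsinolysis, a Gly-Gly dipeptide
isopeptide-bonded to the substrate lysine. All mass arithmetic derives from
a single embedded atomic-mass table (monoisotopic masses from the standard
atomic-mass evaluation, average masses from IUPAC standard atomic weights)
and residue elemental compositions, so the remnant mass is computed, not
quoted: Δm(GG) = mass(C₄H₆N₂O₂) = 114.04293 Da monoisotopic (both glycines
are in amide linkage; no water term), 114.10 Da average. Deriving residue
masses from the same atomic constants makes Δm(GG) = 2·m(Gly residue) an
exact identity, which property tests exploit.

Fixed cysteine carbamidomethylation (+57.02146 Da) and variable methionine
oxidation (+15.99491 Da) are available as modification deltas; internal
arithmetic is full double precision, display follows the conventional
2 d.p. (monoisotopic) / 1 d.p. (average).

## Digestion

Trypsin cuts after K/R except before P. A GG-modified lysine is refractory:
its junction is removed from the cleavage-site set entirely, so it is
neither cut nor counted against the missed-cleavage budget (default
maximum 2). The exemption is a deliberate choice — how commercial engines
book-keep blocked junctions is not documented — and it is what keeps long
signature peptides spanning a modified K reachable under a two-missed-
cleavage limit. Coordinates are 1-based; no N-terminal methionine
stripping (site numbering must match K12-style labels on peptides that
start at residue 1).

Candidate enumeration hypothesises each lysine independently: a candidate
peptide carries exactly one GG, which blocks only its own junction. This
makes targeted mode (restricted to known sites) and discovery mode (all
lysines) the same operation on different target sets, and it guarantees
that adding a target site never removes candidates of another (an
all-sites-blocked digest violates this: two adjacent blocked lysines merge
their covering peptides into one). The cost is that doubly-modified
peptides are never hypothesised — a known limitation, acceptable because
multiply-ubiquitinated tryptic peptides are rare and each site still has
singly-modified covering peptides.

## Fragments

Full b/y ladders (indices 1..n−1) at fragment charges {1, 2}; 2+ fragments
matter for the 3+/4+ precursors an ion trap selects, while informative 3+
fragments are rare there. A fragment is **branched** iff its residue span
covers a GG site; its m/z exceeds the unmodified homolog by 114.04293/z.
The remnant is inert mass: fragmentation within the Gly-Gly branch is not
modelled (no masses to model it with), and neutral losses, a-ions and
internal ions are out of scope since the acceptance rule counts branched
b/y evidence only. The complementarity identity b\_i + y\_{n−i} =
M + 2·m\_p (singly charged) is enforced as an internal oracle.

## Search

* **XIC screening**: per MS1 scan, summed intensity within ±0.3 m/z of the
  candidate precursor; candidates with no signal above
  `xic_min_intensity` (default 0, i.e. any signal) are dropped; the apex
  retention time is kept. Screening is an exact vectorised equivalent of
  the per-scan definition (`extract_xic`), verified by test.
* **Pairing**: a spectrum is tried against a candidate iff charges agree,
  precursor m/z is within the XIC halfwidth, and retention time is within
  ±30 s of the apex.
* **Matching**: greedy nearest-first one-to-one assignment of theoretical
  ions to peaks within 0.5 Da; ties break toward the lower-index fragment,
  then the lower-m/z peak — deterministic and, on small spectra, equal to
  the maximum bipartite matching (tested against an exhaustive oracle).
  Matched fragments are counted as distinct (series, index) species: the
  1+ and 2+ states of b₅ are one ion's evidence, not two.
* **Site acceptance**: ≥4 distinct branched species matched AND matched
  peaks carry ≥70 % of total spectrum intensity
  (`min_scored_intensity_fraction`). The intensity condition is a
  transparent rendition of the usual minimum-scored-peak-intensity
  identification criterion; without it, near-isobaric tryptic peptides
  that collide in precursor m/z (common at 0.5 Da fragment tolerance over
  thousands of discovery candidates) chance-match four branched ions while
  explaining almost none of the spectrum.
* **Ambiguity**: when one spectrum matches several site isoforms of the
  same peptide span, the isoform with more matched branched ions wins;
  exact ties are all reported, flagged ambiguous.
* **Protein filter**: distinct peptide species with best score ≥7
  contribute; a protein passes with ≥2 contributors and summed score ≥14.
  The surrogate peptide score, 10·(matched species / theoretical species)
  + 2·(branched matches), is monotone in evidence and puts a clean full
  ladder far above threshold (score ≈ 10 + 2·branched) while a handful of
  chance matches sit near it.

Defaults (1.6 Da precursor window in Da-space after charge deconvolution,
0.5 Da fragment tolerance, ±0.3 m/z XIC, charges 2+–4+, 2 missed
cleavages, 7/14 score thresholds) are the ion-trap settings this workflow
is designed around; all are `SearchConfig` fields.

## Synthetic data

The generator emulates what the search assumes: i.i.d. residues from
Swiss-Prot average amino-acid frequencies (≈5.8 % lysine), GG sites drawn
uniformly without replacement over lysines, one Gaussian elution profile
(σ = 5 s) per candidate peptide × charge at a uniform apex within a
3600 s run (a 60-min gradient) sampled every 2 s, and one MS2 spectrum
near each apex: full b/y ladders with per-ion dropout
(`fragment_dropout_prob`), N(0, `mass_jitter_sd`) m/z jitter, log-normal
intensities, uniform noise peaks, plus distractor spectra from unmodified
tryptic peptides. Defaults: 20 proteins of 200–400 residues, 10 sites,
10 % dropout, 20 noise peaks, 0.02 Da jitter, seed 1; every stochastic
path flows from one `numpy` Generator seeded from `SimConfig.seed`.

Not modelled: isotope envelopes, chromatographic drift, co-isolation
chimeras, chemical noise, intensity structure along the ladder. Passing
tests therefore demonstrate that the search logic is correct under its own
data model, not that real ion-trap data would be recovered as cleanly.

## Recovery scoring

Site-level exact match on (accession, position) over accepted calls;
recall = found∩true/true, precision = found∩true/found. With no accepted
calls precision is undefined and reported as 1.0 with a
`precision_defined=False` flag. On clean data (no dropout, noise or
jitter) the pipeline attains recall 1.0 and precision 1.0 (checked over
multiple seeds); recall degrades monotonically in dropout (checked as a
20-seed mean over scaled-down proteomes: 3 proteins of 60–100 residues,
2 sites — sizes chosen to keep the whole suite fast).

## Reporting fixtures

The three packaged TSVs are row-faithful transcriptions of curated protein
tables (50 specifically bound proteins in seven functional groups; 59
control identifications; 12 signature-bearing proteins with 35 K-sites).
Tallies count printed rows, not unique accessions — one tubulin accession
(Q6P9V9) appears twice and is preserved — so the group sums reproduce the
tables' own arithmetic (13 + 24 + 1 + 3 + 2 + 4 + 3 = 50). Transcription
normalisations: decimal commas → dots in two scores, line-wrap spaces
removed inside peptide strings, the three ubiquitin-related rows'
undetermined localization coded `unknown`. The signature-bearing fraction
is printed exactly (12/50 = 24.0 %) rather than as the conventional
"about 20 %". Localization split: M → intramitochondrial; EM and PM →
extramitochondrial (2 vs 10 on the packaged tables).

## Network

Edge lists are user-supplied TSVs (interaction databases are queried by
the user; versions drift and this package stays offline). Thresholding is
inclusive (≥, the usual database convention, default 0.7). Clustering
embeds the confidence-weighted adjacency via the eigenvectors of the
normalised Laplacian into min(k, n−1) dimensions and runs k-means
(fixed seed, n_init = 10, default k = 5); disconnected components separate
exactly in that embedding. A per-node filter (mean incident confidence
≥0.9) is available but optional — the underlying requirement it renders is
ambiguous, and this interpretation is documented rather than claimed
faithful. Cluster ids are relabelled 1..k in order of first member for
determinism.

## Known limitations

* One GG per candidate peptide (see Digestion).
* No decoy search / FDR estimation — the acceptance rule and intensity
  criterion are the only specificity controls.
* MGF and tidy CSV are the only I/O formats (mzML deliberately out of
  scope); malformed MGF blocks are reported by file and block title, not
  line number.
* The surrogate score is calibrated to the 7/14 thresholds on clean
  ladders; it is not comparable to any commercial engine's score scale.
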