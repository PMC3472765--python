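# Curated control table: proteins identified after the same avidin-agarose
# chromatography of mitochondria incubated WITHOUT biotinylated ubiquitin,
# transcribed as printed (row order and accession spellings preserved).
name	accession	sequence_coverage	search_score
rCG50775	EDL86881	11	102.68
type I keratin KA17	Q6IFU8	14	88.22
cytokeratin-8	Q80WH8	9	86.42
keratin complex 2, basic, gene 8	Q10758	9	86.42
hypothetical protein LOC683313	Q63282	11	85.15
rCG50690	EDL86882	27	76.25
Keratin, type II cytoskeletal 75	Q6IG05	11	71.38
keratin complex 1, acidic, gene 14	NP_001008751	8	63.05
type I keratin KA22	Q6IFU7	9	62.98
similar to keratin complex 2, basic, gene 6a isoform 1	NP_001094477	7	61.64
rCG50520	EDL86873	4	60.01
rCG23467, isoform CRA a	G3V8B0	2	59.00
rCG23609, isoform CRA b	EDM14209	2	59.00
type II keratin Kb15	Q6IFZ4	7	56.92
type I keratin KA15	Q6IFV3	8	56.63
type II keratin Kb39	Q6IG01	4	56.21
rCG34382, isoform CRA_a	G3V6D8	2	56.00
type I keratin KA16	Q6IFU9	9	55.18
rCG33578	EDM06024	12	52.72
type II keratin Kb36	Q6IG03	6	46.15
type II keratin Kb1	Q6IMF3	7	45.54
type I keratin KA11	Q6IFV0	5	45.00
Krt1-19 protein	Q63279	5	41.32
keratin complex 1, acidic, gene 19, isoform CRA b	EDM06018	8	41.32
rCG34382, isoform CRA b	EDM04783	2	40.63
rCG33626	EDM04786	2	37.50
myelin basic protein, isoform CRA a	Q63327	10	34.60
rCG23467, isoform CRA b	EDM14212	2	29.34
PREDICTED: similar to type II keratin Kb36	NP_001008808	6	28.42
keratin complex 1, acidic, gene 19, isoform CRA c	EDM06019	6	27.10
myelin basic protein isoform 1	P02688-1	10	27.03
myelin basic protein	Q80Z98	10	27.03
myelin basic protein isoform 2	P02688-2	12	27.03
myelin basic protein isoform 4	P02688-4	13	27.03
rCG34505	EDM05987	2	25.35
myelin basic protein, isoform CRA d	Q5XFW	7	23.60
myelin basic protein, isoform CRA c	G5E945	8	23.60
keratin 13	Q6IFV4	3	23.44
rCG33575	EDM04790	2	22.89
proteolipid protein	P63081	7	20.85
type II keratin Kb2	Q6IG02	2	20.30
Tubulin, alpha 1A	P68370	5	19.83
tubulin, alpha 1C	Q6AYZ1	5	19.83
rCG50513, isoform CRA b	EDL87016	7	19.83
rCG50513, isoform CRA a	EDL87015	7	19.83
keratin complex 1, acidic, gene 12	Q5BJY9	1	17.88
rCG34869	EDM05985	3	17.88
keratin 19	Q63279	3	17.88
type II keratin Kb9	Q6IFZ5	3	17.11
rCG62531, isoform CRA d	EDM00590	9	16.42
myelin basic protein isoform 3	P02688-3	6	16.03
myelin basic protein isoform 5	P02688-5	7	16.03
rCG44184, isoform CRA a	EDL98317	4	15.98
rCG29914, isoform CRA b	EDM01924	5	15.23
Tpi 1 protein	P48500	6	15.23
rCG29914, isoform CRA a	EDM01923	6	15.23
rCG47746, isoform CRA b	EDM13157	13	14.99
keratin 20	P25030	2	14.22
rCG33887, isoform CRA a	EDM06013	14	14.22
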