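# Curated table of specifically bound proteins (avidin-agarose pull-down after
# preincubation with biotinylated ubiquitin), transcribed as printed.
# Decimal commas in the source scores were normalized to dots.
# Localization: M mitochondrial, EM extramitochondrial, PM plasma membrane,
# unknown where the source marks localization as undetermined.
group	name	accession	sequence_coverage	search_score	localization
energy_carbohydrate	Pyruvate carboxylase, mitochondrial precursor	P52873	25	285.19	M
energy_carbohydrate	ATP synthase subunit beta, mitochondrial precursor	P10719	47	231.07	M
energy_carbohydrate	ATP synthase subunit alpha, mitochondrial precursor	P15999	30	163.32	M
energy_carbohydrate	Sodium/potassium-transporting ATP-ase subunit alpha-3	P06687	13	130.82	PM
energy_carbohydrate	Glyceraldehyde-3-phosphate dehydrogenase	P04797	14	48.89	EM
energy_carbohydrate	ADP/ATP translocase 2	Q09073	11	42.59	M
energy_carbohydrate	Creatine kinase M-type	P00554	12	56.1	M
energy_carbohydrate	Sodium/potassium-transporting ATP-ase subunit alpha-2 precursor	P06686	5	37.89	PM
energy_carbohydrate	ATP synthase subunit O, mitochondrial precursor	Q06647	11	34.75	M
energy_carbohydrate	Sodium/potassium-transporting ATP-ase subunit alpha-1, precursor	P06685	2	21.46	PM
energy_carbohydrate	ATP synthase subunit d, mitochondrial	P31399	10	16.97	M
energy_carbohydrate	Pyruvate dehydrogenase E1 component subunit beta, mitochondrial precursor	P49432	4	15.32	M
energy_carbohydrate	Dihydrolipoyllysine-residue acetyltransferase component of pyruvate dehydrogenase complex, mitochondrial precursor	P08461	2	14.02	M
cytoskeleton_exocytosis	Keratin type I cytoskeletal 10	Q6IFW6	19	176.37	EM
cytoskeleton_exocytosis	Keratin type II cytoskeletal 5	Q6P6Q2	14	165.65	EM
cytoskeleton_exocytosis	Keratin type II cytoskeletal 1	Q6IMF3	9	124.82	EM
cytoskeleton_exocytosis	Keratin type I cytoskeletal 42	Q6IFU7	16	118.43	EM
cytoskeleton_exocytosis	Keratin type II cytoskeletal 6A	Q4FZU2	13	115.79	EM
cytoskeleton_exocytosis	Tubulin alpha-1B chain	Q6P9V9	27	111.39	EM
cytoskeleton_exocytosis	Keratin type I cytoskeletal 14	Q6IFV1	9	80.83	EM
cytoskeleton_exocytosis	Neurofilament light polypeptide	P19527	13	71.54	EM
cytoskeleton_exocytosis	Tubulin beta-2B chain	Q3KRE8	12	62.92	EM
cytoskeleton_exocytosis	Tubulin beta-2A chain	Q85108	12	62.92	EM
cytoskeleton_exocytosis	Glial fibrillary acidic protein	P47819	14	57.15	EM
cytoskeleton_exocytosis	Tubulin beta-5 chain	P69897	12	54.58	EM
cytoskeleton_exocytosis	Tubulin beta-3 chain	Q4QRB4	10	48.33	EM
cytoskeleton_exocytosis	Myosin-4	Q29RW1	2	45.07	EM
cytoskeleton_exocytosis	Alpha-internexin	P23565	11	43.84	EM
cytoskeleton_exocytosis	Actin, alpha skeletal muscle	P68136	11	43.17	EM
cytoskeleton_exocytosis	Tubulin alpha-1B chain	Q6P9V9	9	39.35	EM
cytoskeleton_exocytosis	Tubulin alpha-1A chain	P68370	9	39.35	EM
cytoskeleton_exocytosis	Myosin-6	P02563	2	37.23	EM
cytoskeleton_exocytosis	Neurofilament medium polypeptide	P12839	5	35.80	EM
cytoskeleton_exocytosis	Myosin-3	P12847	1	34.23	EM
cytoskeleton_exocytosis	Syntaxin-1B	P61265	10	26.19	EM
cytoskeleton_exocytosis	Synaptotagmin-1	P21707	3	18.57	EM
cytoskeleton_exocytosis	Spectrin alpha chain, brain	P16086	1	17.02	EM
protective	60 kDa heat shock protein, mitochondrial precursor	P63039	9	29.87	M
signal_regulation	Calcium/calmodulin-dependent protein kinase	P11275	7	39.65	EM
signal_regulation	2',3'-cyclic-nucleotide 3'-phosphodiesterase	P13233	8	46.16	EM
signal_regulation	Pro-associated protein kinase 2	Q62868	1	19.53	EM
fatty_acid	Propionyl-CoA carboxylase beta chain, mitochondrial precursor	P07633	13	67.94	M
fatty_acid	Propionyl-CoA carboxylase alpha chain, mitochondrial precursor	P14882	5	37.33	M
transporters	Excitatory amino acid transporter 1	P24942	6	34.57	PM
transporters	Excitatory amino acid transporter 2	P31596	2	26.35	PM
transporters	Glial high affinity glutamate transporter isoform a	G3V6R2	2	25.7	PM
transporters	sodium-dependent high affinity glutamate transporter GLT-1A	G3V6R0	2	26.0	PM
ubiquitin_related	polyubiquitin	P0CG51	51	54.99	unknown
ubiquitin_related	ubiquitin C	Q63429	4	44.01	unknown
ubiquitin_related	Ubc protein	Q5FWT0	10	44.01	unknown
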