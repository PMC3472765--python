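# Curated table of proteins carrying GG ubiquitination signatures, transcribed
# as printed. Peptides and sites are pipe-separated, paired by position;
# lowercase 'm' in a peptide marks an oxidized methionine as printed.
# Line-wrap spaces inside printed peptide strings were removed.
name	accession	acronym	n_peptides	sequence_coverage	search_score	peptides	sites
Pyruvate carboxylase, mitochondrial precursor	P52873	Pc	18	25	285.19	SGEGMGIRLDNASAFQGAVISPHYDSLLVKVIAHGKDHPTAATKMSR|EVKKAYVEANQMLGDLIKVTPSSKIVGDLAQFMVQNGLSR|SSTAPVASPNVRRLEYKPIKKVMVANR	K442|K891|K35
ATP synthase subunit alpha, mitochondrial precursor	P15999	Atp5a1	11	30	163.32	ELIIGDRQTGKTSIAIDTIINQK|VGSAAQTRAmKQVAGTMKLELAQYREVAAFAQFGSDLDAATQQLLSR|VVDALGNAIDGKGPVGSKIR|AMKQVAGTMKLELAQYREVAAFAQFGSDLDAATQQLLSR	K218|K434|K161|K427
Sodium/potassium-transporting ATP-ase subunit alpha-3	P06687	Atp1a3	9	13	130.82	EKLENMKKEMEMNDHQLSVSELEQKYQTSATK|RDTAGDASESALLKCIELSCGSVRKMR|GFAFDCDDVNFTTDNLCFVGLMSMIDPPRAAVPDAVGKCR	K63|K456|K595
Keratin type I cytoskeletal 10	Q6IFW6	Krt10	14	19	176.37	NELTEMKRTLQTLEIELQSLLAMK|TIEDLKSKILAATVDNANVLLQIDNAR	K298|K182
Keratin type II cytoskeletal 5	Q6P6Q2	Krt5	20	14	165.65	IKTQEREQIKTLNNKFASFIDK|EYQELMNTKLALDVEIATYR|NKYEDEINKRTEmENEFVLIKK|ALNNKFASFIDKVRFLEQQNQVLETKWELLQQLDQNNSR	K172|K456|K185|K165
Keratin type II cytoskeletal 1	Q6IMF3	Krt1	9	9	124.82	LALDMEIATYRKLLEGEEIRMSGECTPNVSVSVSTSHTSMSGTSSR|MLREHQELMSMKLALDIEIATYR|TTAENEFVVLKKDVDAAYMSKVELQAKVDALDGEIK	K483|K423|K139
Myosin-4	Q29RW1	Myh1	4	2	45.07	NTQGMLKDTQLHLDDALRGQDDLKEQLAMVERR|IKKKMEGDLNEMEIQLNHANRQAAEAIR|SGLYKLTGAVMHYGNMKFKQK|KLEGDLKLAQESTMDIENDKQQLDEKLK|AFMGVKNWPWMKLYFKIKPLLK|FQLEAKIKEVTERAEDEEEINAELTAK|KMEGDLNEMEIQLSHANRMAAEAQKQVKEAR|GKAEAHFSLVHYAGTVDYNIIGWLDKNK	K1655|K1619|K366|K1083|K838|K919|K1644|K599
Actin, alpha skeletal muscle	P68136	Acta2	3	11	43.17	KDLYANNVMSGGTTMYPGIADRMQKEITALAPSTMK|AVFPSIVGRPRHQGVMVGMGQKDSYVGDEAQSKR	K293|K50
Myosin-6	P02563	Myh6	3	2	37.23	QREEQAEPDGTEDADKSAYLMGLNSADLLK	K383
Spectrin alpha chain, brain	P16086	Spna2	2	1	17.02	MQHNLEQQIQARNTTGVTEEALKEFSMMFKHFDK|SCKKFMLFREANELQQWINEKEAALTSEEVGADLEQVEVLQK|DLNSQADSLMTSSAFDTSQVKEKR	K2333|K1110|K1738
2',3'-cyclic-nucleotide 3'-phosphodiesterase	P13233	Cpn	3	8	46.16	GKLYSLGKGRWMLSLAKK	K370
Excitatory amino acid transporter 2	P31596	Slc1a2	2	2	26.35	MASTEGANNMPKQVEVRMHDSHLSSEEPKHRNLGMR	K12
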