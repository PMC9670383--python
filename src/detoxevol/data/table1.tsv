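# Curated detoxification gene complements per species, superfamily and
# clan/class.  Species tags: Rpro = Rhodnius prolixus, Clec = Cimex
# lectularius, Hhal = Halyomorpha halys, Nvir = Nezara viridula (transcriptome),
# Nlug = Nilaparvata lugens.  Totals are never stored; they are recomputed.
species	superfamily	group	count
Rpro	CYP	Mitochondrial	7
Rpro	CYP	CYP2	6
Rpro	CYP	CYP3	53
Rpro	CYP	CYP4	47
Rpro	CCE	HPP	43
Rpro	CCE	Dietary	0
Rpro	CCE	ND	20
Rpro	GST	Delta	1
Rpro	GST	Epsilon	0
Rpro	GST	Omega	1
Rpro	GST	Sigma	7
Rpro	GST	Theta	3
Rpro	GST	Zeta	1
Rpro	GST	Microsomal	1
Clec	CYP	Mitochondrial	7
Clec	CYP	CYP2	6
Clec	CYP	CYP3	30
Clec	CYP	CYP4	12
Clec	CCE	HPP	30
Clec	CCE	Dietary	0
Clec	CCE	ND	16
Clec	GST	Delta	2
Clec	GST	Epsilon	0
Clec	GST	Omega	1
Clec	GST	Sigma	6
Clec	GST	Theta	2
Clec	GST	Zeta	1
Clec	GST	Microsomal	3
Hhal	CYP	Mitochondrial	8
Hhal	CYP	CYP2	6
Hhal	CYP	CYP3	75
Hhal	CYP	CYP4	43
Hhal	CCE	HPP	57
Hhal	CCE	Dietary	0
Hhal	CCE	ND	15
Hhal	GST	Delta	2
Hhal	GST	Epsilon	0
Hhal	GST	Omega	3
Hhal	GST	Sigma	17
Hhal	GST	Theta	3
Hhal	GST	Zeta	1
Hhal	GST	Microsomal	3
Nvir	CYP	Mitochondrial	6
Nvir	CYP	CYP2	4
Nvir	CYP	CYP3	41
Nvir	CYP	CYP4	32
Nvir	CCE	HPP	45
Nvir	CCE	Dietary	0
Nvir	CCE	ND	7
Nvir	GST	Delta	0
Nvir	GST	Epsilon	0
Nvir	GST	Omega	2
Nvir	GST	Sigma	9
Nvir	GST	Theta	3
Nvir	GST	Zeta	1
Nvir	GST	Microsomal	1
Nlug	CYP	Mitochondrial	11
Nlug	CYP	CYP2	9
Nlug	CYP	CYP3	16
Nlug	CYP	CYP4	34
Nlug	CCE	HPP	25
Nlug	CCE	Dietary	5
Nlug	CCE	ND	20
Nlug	GST	Delta	2
Nlug	GST	Epsilon	4
Nlug	GST	Omega	1
Nlug	GST	Sigma	4
Nlug	GST	Theta	1
Nlug	GST	Zeta	1
Nlug	GST	Microsomal	2
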