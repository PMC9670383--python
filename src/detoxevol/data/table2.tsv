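# Per-branch duplication and loss counts by family group, from manual
# gene-tree / species-tree reconciliation of the five-species analysis.
# Branch labels: terminal branches carry the species tag; CR = Clec+Rpro
# ancestor, HN = Hhal+Nvir ancestor, HET = (Clec+Rpro)+(Hhal+Nvir)
# (the heteropteran ancestor).  Family groups: MIT = mitochondrial CYP clan,
# CYP2/CYP3/CYP4 = the other CYP clans, GST and CCE = whole superfamilies.
# Only the cells are stored; totals are recomputed (see
# table2_printed_totals.tsv for the totals as originally printed).
branch	event	group	count
Clec	Duplications	MIT	0
Clec	Duplications	CYP2	0
Clec	Duplications	CYP3	17
Clec	Duplications	CYP4	0
Clec	Duplications	GST	2
Clec	Duplications	CCE	24
Rpro	Duplications	MIT	0
Rpro	Duplications	CYP2	0
Rpro	Duplications	CYP3	34
Rpro	Duplications	CYP4	38
Rpro	Duplications	GST	2
Rpro	Duplications	CCE	39
CR	Duplications	MIT	0
CR	Duplications	CYP2	0
CR	Duplications	CYP3	5
CR	Duplications	CYP4	3
CR	Duplications	GST	0
CR	Duplications	CCE	0
Hhal	Duplications	MIT	0
Hhal	Duplications	CYP2	0
Hhal	Duplications	CYP3	25
Hhal	Duplications	CYP4	11
Hhal	Duplications	GST	5
Hhal	Duplications	CCE	33
Nvir	Duplications	MIT	0
Nvir	Duplications	CYP2	0
Nvir	Duplications	CYP3	6
Nvir	Duplications	CYP4	9
Nvir	Duplications	GST	1
Nvir	Duplications	CCE	5
HN	Duplications	MIT	2
HN	Duplications	CYP2	0
HN	Duplications	CYP3	43
HN	Duplications	CYP4	27
HN	Duplications	GST	12
HN	Duplications	CCE	44
HET	Duplications	MIT	0
HET	Duplications	CYP2	0
HET	Duplications	CYP3	15
HET	Duplications	CYP4	5
HET	Duplications	GST	7
HET	Duplications	CCE	9
Nlug	Duplications	MIT	3
Nlug	Duplications	CYP2	1
Nlug	Duplications	CYP3	9
Nlug	Duplications	CYP4	21
Nlug	Duplications	GST	5
Nlug	Duplications	CCE	30
Clec	Losses	MIT	1
Clec	Losses	CYP2	1
Clec	Losses	CYP3	10
Clec	Losses	CYP4	2
Clec	Losses	GST	2
Clec	Losses	CCE	7
Rpro	Losses	MIT	0
Rpro	Losses	CYP2	1
Rpro	Losses	CYP3	4
Rpro	Losses	CYP4	5
Rpro	Losses	GST	3
Rpro	Losses	CCE	8
CR	Losses	MIT	0
CR	Losses	CYP2	0
CR	Losses	CYP3	3
CR	Losses	CYP4	3
CR	Losses	GST	0
CR	Losses	CCE	5
Hhal	Losses	MIT	0
Hhal	Losses	CYP2	0
Hhal	Losses	CYP3	6
Hhal	Losses	CYP4	5
Hhal	Losses	GST	1
Hhal	Losses	CCE	4
Nvir	Losses	MIT	2
Nvir	Losses	CYP2	2
Nvir	Losses	CYP3	22
Nvir	Losses	CYP4	11
Nvir	Losses	GST	10
Nvir	Losses	CCE	14
HN	Losses	MIT	1
HN	Losses	CYP2	1
HN	Losses	CYP3	7
HN	Losses	CYP4	0
HN	Losses	GST	1
HN	Losses	CCE	5
HET	Losses	MIT	1
HET	Losses	CYP2	2
HET	Losses	CYP3	1
HET	Losses	CYP4	5
HET	Losses	GST	0
HET	Losses	CCE	3
Nlug	Losses	MIT	0
Nlug	Losses	CYP2	1
Nlug	Losses	CYP3	1
Nlug	Losses	CYP4	1
Nlug	Losses	GST	1
Nlug	Losses	CCE	5
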