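# Totals as printed in the source table, kept separately so recomputed sums
# can be checked against them.  Rows with kind=branch give the printed
# per-branch row total for one event type; rows with kind=group give the
# printed duplications+losses column total for one family group; the
# kind=grand row is the printed grand total.  Two printed values disagree
# with the stored cells (the Nlug duplications row total and the grand
# total); fixture_discrepancies() reports them.
kind	branch	event	group	printed_total
branch	Clec	Duplications	-	43
branch	Rpro	Duplications	-	113
branch	CR	Duplications	-	8
branch	Hhal	Duplications	-	74
branch	Nvir	Duplications	-	21
branch	HN	Duplications	-	128
branch	HET	Duplications	-	36
branch	Nlug	Duplications	-	33
branch	Clec	Losses	-	23
branch	Rpro	Losses	-	21
branch	CR	Losses	-	11
branch	Hhal	Losses	-	16
branch	Nvir	Losses	-	61
branch	HN	Losses	-	15
branch	HET	Losses	-	12
branch	Nlug	Losses	-	9
group	-	-	MIT	10
group	-	-	CYP2	9
group	-	-	CYP3	208
group	-	-	CYP4	146
group	-	-	GST	52
group	-	-	CCE	235
grand	-	-	-	624
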