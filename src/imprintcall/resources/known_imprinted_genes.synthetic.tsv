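gene_id	chrom	start	end	strand	is_known_imprinted	cluster
Peg12	7	62400000	62420000	-	True	Snrpn
Magel2	7	62370000	62390000	-	True	Snrpn
Ndn	7	62340000	62360000	-	True	Snrpn
Mkrn3	7	62410000	62430000	-	True	Snrpn
Snrpn	7	60000000	60100000	+	True	Snrpn
Snhg14	7	60100000	60800000	+	True	Snrpn
Slc22a3	17	12400000	12500000	+	True	Airn/Igf2r
Pde10a	17	8500000	8900000	+	True	Airn/Igf2r
Igf2r	17	12680000	12780000	-	True	Airn/Igf2r
Airn	17	12740000	12830000	+	True	Airn/Igf2r
Tssc4	7	143060000	143070000	+	True	Kcnq1
Ascl2	7	142960000	142970000	-	True	Kcnq1
Kcnq1ot1	7	143200000	143290000	-	True	Kcnq1
Cdkn1c	7	143450000	143460000	-	True	Kcnq1
Phlda2	7	143480000	143490000	-	True	Kcnq1
Jade1	3	41560000	41620000	+	True	Jade1
Platr4	3	41640000	41660000	+	True	Jade1
Sfmbt2	2	10310000	10440000	+	True	.
Smoc1	12	81080000	81200000	+	True	.
Epop	11	100560000	100570000	-	True	.
Spp1	5	104430000	104440000	+	True	.
H13	2	152660000	152700000	+	True	.
Etv6	6	134120000	134260000	+	True	.
Gab1	8	80680000	80800000	-	True	.
Slc38a4	15	96990000	97050000	-	True	.
Gatm	2	122590000	122610000	-	True	.
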