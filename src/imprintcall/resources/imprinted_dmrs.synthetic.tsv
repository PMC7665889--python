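chrom	start	end	name	region_class
7	60003000	60007000	Snrpn_DMR	germline_DMR
17	12742000	12746000	Igf2r_DMR	germline_DMR
7	143294000	143298000	Kcnq1ot1_DMR	germline_DMR
7	143100000	143104000	Kcnq1-Intergenic1_DMR	secondary_DMR
7	143150000	143154000	Kcnq1-Intergenic2_DMR	secondary_DMR
2	10312000	10316000	Sfmbt2_DMR	secondary_DMR
3	41562000	41566000	Jade1_DMR	secondary_DMR
7	62402000	62405000	Peg12_DMR	secondary_DMR
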