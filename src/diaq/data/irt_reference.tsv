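peptide_id	irt
LGGNEQVTR	-24.92
GAGSSEPVTGLDAK	0.00
VEATFGVDESNAK	12.39
YILAGVENSK	19.79
TPVISGGPYEYR	28.71
TPVITGAPYEYR	33.38
DGLDAASYYAPVR	42.26
ADVTPADFSEWSK	54.62
GTFIIDPGGVIR	70.52
GTFIIDPAAVIR	87.23
LFLQFGAQGSPFLK	100.00
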