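ligand_id	default	cutoff_2016
TNFa	0.871	0.869
TRAIL	0.713	0.705
4-1BBL	0.699	0.392
LIGHT	0.590	0.709
TNFb	0.563	0.515
TNFSF13	0.552	0.454
TNFSF4	0.484	0.118
TNFSF12	0.271	0.101
TNFg	0.261	0.311
CD70	0.233	0.353
CD153	0.223	0.096
TNFSF11	0.215	0.265
TNFSF13B	0.204	0.253
TNFSF18	0.163	0.276
FASLG	0.161	0.155
EDA	0.150	0.158
TNFSF15	0.098	0.089
CD40LG	0.081	0.082
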