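# config_hash=4cb1695a2659e456
coverage_bin	deg_3to5	endo	deg_5to3	ambiguous_internal
[0.0,0.1)	513	534	297	0
[0.1,0.2)	964	988	513	0
[0.2,0.3)	1083	936	559	0
[0.3,0.4)	1091	958	534	0
[0.4,0.5)	972	955	546	0
[0.5,0.6)	1049	998	553	0
[0.6,0.7)	1015	943	531	0
[0.7,0.8)	1044	901	513	0
[0.8,0.9)	945	0	512	0
[0.9,1.0)	0	0	0	0
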