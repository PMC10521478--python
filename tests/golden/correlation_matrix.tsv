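# config_hash=4cb1695a2659e456
	Exo_1	Exo_2	Exo_3	MV_1	MV_2	MV_3
Exo_1	1	0.898682	0.889616	0.522586	0.506398	0.482065
Exo_2	0.898682	1	0.912691	0.499761	0.485301	0.477789
Exo_3	0.889616	0.912691	1	0.506091	0.486941	0.48477
MV_1	0.522586	0.499761	0.506091	1	0.772031	0.766477
MV_2	0.506398	0.485301	0.486941	0.772031	1	0.72374
MV_3	0.482065	0.477789	0.48477	0.766477	0.72374	1
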