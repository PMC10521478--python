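# config_hash=4cb1695a2659e456
sample_id	biotype	composition_percentage	read_count_ratio
Exo_1	protein_coding	66.0714	68.6683
Exo_1	retained_intron	11.7857	10.3758
Exo_1	lncRNA	8.21429	7.88399
Exo_1	nonsense_mediated_decay	5.71429	4.84069
Exo_1	processed_transcript	2.14286	2.69608
Exo_1	misc_RNA	2.5	3.5335
Exo_1	rRNA	3.57143	2.00163
Exo_1	other	0	0
Exo_2	protein_coding	66.0777	68.731
Exo_2	retained_intron	11.6608	9.72589
Exo_2	lncRNA	8.12721	8.52792
Exo_2	nonsense_mediated_decay	5.65371	4.71066
Exo_2	processed_transcript	2.12014	2.51777
Exo_2	misc_RNA	2.82686	3.20812
Exo_2	rRNA	3.53357	2.57868
Exo_2	other	0	0
Exo_3	protein_coding	66.3121	66.5853
Exo_3	retained_intron	11.7021	11.396
Exo_3	lncRNA	8.15603	8.14001
Exo_3	nonsense_mediated_decay	5.67376	4.66015
Exo_3	processed_transcript	2.12766	3.5002
Exo_3	misc_RNA	2.83688	3.3781
Exo_3	rRNA	3.19149	2.34025
Exo_3	other	0	0
MV_1	protein_coding	67.0251	72.2165
MV_1	retained_intron	11.828	9.09091
MV_1	lncRNA	8.24373	5.10725
MV_1	nonsense_mediated_decay	5.37634	4.12666
MV_1	processed_transcript	2.15054	3.3095
MV_1	misc_RNA	2.15054	3.32993
MV_1	rRNA	3.22581	2.8192
MV_1	other	0	0
MV_2	protein_coding	66.6667	68.1447
MV_2	retained_intron	12.3188	11.32
MV_2	lncRNA	7.6087	7.51941
MV_2	nonsense_mediated_decay	5.43478	4.4953
MV_2	processed_transcript	2.17391	3.00368
MV_2	misc_RNA	2.53623	3.90274
MV_2	rRNA	3.26087	1.61422
MV_2	other	0	0
MV_3	protein_coding	67.0251	73.9771
MV_3	retained_intron	11.828	9.00164
MV_3	lncRNA	7.8853	6.19885
MV_3	nonsense_mediated_decay	5.37634	4.27578
MV_3	processed_transcript	2.15054	2.8437
MV_3	misc_RNA	2.50896	1.96399
MV_3	rRNA	3.22581	1.73895
MV_3	other	0	0
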