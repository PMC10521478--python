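# config_hash=4cb1695a2659e456
sample_id	group	n_input_reads	n_qc_removed	n_reads	mean_length	median_length	n50	max_length	mean_quality
Exo_1	Exo	5000	104	4896	445.278	307	658	3885	11.8091
Exo_2	Exo	5000	75	4925	449.994	306	671	3885	11.7846
Exo_3	Exo	5000	86	4914	442.493	300	671	3885	11.8278
MV_1	MV	5000	105	4895	395.523	269	600	3885	11.7953
MV_2	MV	5000	106	4894	416.583	270.5	658	3885	11.7913
MV_3	MV	5000	112	4888	374.803	259	548	3885	11.7777
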