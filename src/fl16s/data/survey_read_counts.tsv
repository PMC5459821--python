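group	site	sample_id	n_ccs_reads	n_processed_reads
gulf	MN	MN1	44117	30890
gulf	MN	MN2	26018	20453
gulf	MN	MN3	24280	22707
gulf	TA	TA1	46466	44796
gulf	TA	TA2	24445	22974
gulf	TA	TA3	38438	35603
gulf	TL	TL1	25792	25562
gulf	TL	TL2	23307	23120
gulf	TL	TL3	25497	24709
andaman	MT	MT1	44083	43913
andaman	MT	MT2	41612	41384
andaman	MT	MT3	60478	60143
andaman	SM	SM1	45338	44254
andaman	SM	SM2	27841	26307
andaman	SM	SM3	33789	32179
andaman	TC	TC1	25103	24331
andaman	TC	TC2	24009	23374
andaman	TC	TC3	26182	25011
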