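sample_id	group	onset_site	sex	age_years	duration_months	alsfrs_r	biopsied_muscle
S01	control		Male	59			deltoid
S02	control		Female	62			deltoid
S03	control		Male	66			deltoid
S04	control		Female	60			deltoid
S05	control		Female	64			deltoid
S06	control		Female	70			deltoid
S07	control		Male	65			deltoid
S08	ALS	Spinal	Male	73	na	34	quadriceps
S09	ALS	Spinal	Female	72	11	33	quadriceps
S10	ALS	Spinal	Female	59	13	35	deltoid
S11	ALS	Bulbar	Male	54	8	38	deltoid
S12	ALS	Spinal	Male	72	18	35	deltoid
S13	ALS	Spinal	Female	55	9	32	deltoid
S14	ALS	Bulbar	Male	64	na	36	quadriceps
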