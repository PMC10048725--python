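property_id	property_name	positive	negative
100	Direction	GG GC	CA GT TC CC
103	Tilt (RNA)	GA TC	AA TT
119	Roll	CA TG	AT
42	Twist_tilt	AA TT	AG CT
49	Shift_rise	AA TT CC GG	CA TG
5	Tip	TA	CA TG
51	Twist_shift	AA TT	AT CA TG AG CT
55	Tilt_slide	AA TT AT AC GT	TA AG CT
56	Tilt_rise	AA TT
57	Roll_shift	AA TT AC GT	TA AG CT
58	Roll_slide	AT	CA TG
63	Roll	AG CT	CA TG GC
65	Slide	CA TG	AC GT
83	Tilt (DNA-protein complex)	AA TT	CA TG
86	Slide (DNA-protein complex)	AT AC GT	CA TG GA TC
89	Tilt	AG CT	CA TG
90	Roll	CC GG	GC
91	Slide	CA TG
93	Tilt	AG CT CC GG	CA TG
94	Roll	AG CT CC GG	GA TC GC
96	Slide	CA TG
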