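dimer1	dimer2	r_empirical	model_mean	model_std	significance
TT	AA	1.00	0.37	0.10	6.26
AT	AA	-0.56	0.01	0.10	-5.66
AT	TT	-0.56	0.02	0.10	-5.86
TA	AA	-0.63	-0.00	0.11	-5.53
TA	TT	-0.64	0.01	0.10	-6.47
TA	AT	0.69	0.05	0.13	4.98
AC	AA	-0.36	0.04	0.14	-2.89
AC	TT	-0.36	-0.04	0.13	-2.51
AC	AT	0.21	-0.07	0.08	3.49
AC	TA	0.34	-0.02	0.11	3.25
CA	AA	-0.18	0.05	0.11	-2.00
CA	TT	-0.18	0.05	0.12	-1.88
CA	AT	-0.44	-0.05	0.12	-3.24
CA	TA	-0.31	-0.02	0.09	-3.07
TG	AA	-0.18	0.08	0.13	-1.97
TG	TT	-0.18	0.06	0.10	-2.46
TG	AT	-0.44	-0.06	0.12	-3.19
TG	TA	-0.30	-0.06	0.14	-1.69
GT	AA	-0.36	0.04	0.11	-3.49
GT	TT	-0.36	0.05	0.10	-4.03
GT	AT	0.21	-0.01	0.14	1.59
GT	TA	0.34	-0.03	0.13	2.78
AG	AA	-0.15	-0.01	0.12	-1.15
AG	AT	-0.53	0.04	0.12	-4.77
AG	TA	-0.28	0.02	0.14	-2.14
GA	TT	-0.10	-0.02	0.07	-1.10
GA	AT	0.27	0.05	0.10	2.24
GA	TA	-0.19	0.00	0.11	-1.73
TC	AT	0.27	-0.02	0.11	2.78
TC	TA	-0.19	0.05	0.12	-1.94
CT	TT	-0.15	-0.04	0.10	-1.04
CT	AT	-0.53	0.07	0.10	-6.12
CT	TA	-0.28	-0.00	0.13	-2.10
CC	AT	-0.26	-0.09	0.17	-1.03
GG	AT	-0.26	-0.10	0.15	-1.08
GC	CA	-0.02	-0.28	0.16	1.67
GC	TG	-0.01	-0.35	0.09	3.62
GC	GA	0.01	0.30	0.12	-2.41
GC	TC	0.01	0.29	0.21	-1.29
CG	AT	0.49	0.09	0.15	2.66
CG	TA	0.26	0.08	0.16	1.09
CG	GC	0.43	0.54	0.06	-1.78
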