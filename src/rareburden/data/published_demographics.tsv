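variable	case_mean	case_sd	case_n	control_mean	control_sd	control_n	reported_p	sqrt_transformed
Maternal age (years)	27.18	5.33	76	26.02	5.32	43	0.256	0
Gestational age at delivery (weeks)	30.05	4.17	76	38.93	1.16	43	<0.001	0
Neonatal weight (kgs)	1.69	1.59	76	3.14	0.46	43	<0.001	0
Gravidity	3.53	2.04	76	3.25	2.57	43	0.555	1
Parity	1.47	1.57	76	1.35	1.41	43	0.657	1
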