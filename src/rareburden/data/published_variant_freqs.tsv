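gene	variant_id	chrom	pos	ref	alt	effect	minor_allele	aa_position	case_freq	control_freq
AOAH	rs145455591	7	36514524	C	T	nonsense	T	556	0.036	0.026
CARD6	rs150487186	5	40853011	T	G	nonsense	G	560	0.004	0.000
CARD8	rs140826611	19	48231760	-	AA	frameshift	AA	148	0.016	0.006
DEFB1	rs5743490	8	6870777	C	A	nonsense	A	37	0.011	0.000
FUT2	rs601338	19	48703417	G	A	nonsense	A	154	0.374	0.376
FUT2	rs143482452	19	48703041	C	T	nonsense	T	29	0.002	0.000
FUT2	rs1799761	19	48703767	C	-	frameshift	-	271	0.007	0.012
MBL2	rs74754826	10	52768256	G	T	nonsense	T	210	0.011	0.000
NLRP10	rs765522475	11	7961305	C	T	nonsense	T	103	0.002	0.000
NLRP12	rs35064500	19	53795911	C	T	nonsense	T	1017	0.021	0.007
NLRP12	rs776426826	19	53795917	AG	-	frameshift	-	1015	0.002	0.003
NOD2	rs2066847	16	50729867	-	C	frameshift	C	1007	0.004	0.000
TLR10	rs62617795	4	38774483	C	T	nonsense	T	370	0.020	0.016
TLR10	rs140873456	4	38775590	A	G	start_loss	G	1	0.003	0.003
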