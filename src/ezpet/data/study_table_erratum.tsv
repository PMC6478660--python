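patient	reference_ez	visual	spm1	spm2	petanalysis	mri	histopathology	engel
1	R/MT	R/LT	Neg	R/LT	R/MT	R/MTS	MTS	I
2	L/MT	L/MT	Neg	L/LT	L/MT	L/MTS	MTS	I
3	L/MT	L/MT	Neg	L/MT	L/MT	L/MTS	MTS	I
4	L/MT	L/MT	Neg	L/LT	L/MT	L/MTS	MTS	I
5	L/MLT	L/LT	Neg	Neg	L/MT	L/MTS	FCDI+MTS	I
6	L/MT	L/MT	Neg	L/MT	L/MT	L/MTS	FCDIIA	I
7	R/MT	R/MT	Neg	Neg	R/MT	R/MTS	MTS	I
8	R/MT	R/LT	Neg	R/MT	R/MT	R/MTS	MTS	I
9	L/MT	L/MT	Neg	Neg	Neg	L/MTS	MTS	I
10	R/MT	R/MT	Neg	R/MT	R/MT	R/MTS	MTS	II
11	L/MT	L/MT	Neg	Neg	L/LT	L/MTS	Gliosis	I
12	R/MT	R/MT	Neg	R/MT	R/MT	R/MTS	MTS	I
13	L/LT	L/LT	Neg	Neg	R/I	L/LT DNET	Xanthoastr.	II
14	L/LT	L/LT	Neg	L/LT	L/LT	L/LT Gliosis	Gliosis	I
15	R/P	R/P	R/O	R/O	R/P	R/P FCD	FCDII	I
16	L/O	L/O	Neg	Neg	L/O	L/O Gliosis	Gliosis	I
17	R/MT	R/LT	Neg	R/LT	R/LT	Non-L	MTS	I
18	R/MLT	R/MT	Neg	Neg	R/MT	Non-L	FCDIIA+MTS	I
19	L/MLT	R/MT	Neg	Neg	L/MT	Non-L	FCDIIA+MTS	I
20	R/MT	R/LT	Neg	R/LT	L/LT	Non-L	MTS	II
21	R/MT	R/MT	Neg	Neg	L/MT	Non-L	Gliosis	I
22	R/MT	R/LT	Neg	R/MT	R/MT	Non-L	MTS	I
23	R/MT	R/MT	Neg	Neg	R/MT	Non-L	MTS	II
24	L/F	L/F	Neg	L/F	L/F	Non-L	FCDIIA	I
25	R/LT	R/LT	Neg	Neg	L/F	Non-L	FCDI	I
26	R/MLT	R/LT	Neg	R/LT	L/LT	Non-L	Gliosis	I
27	L/MT	L/LT	Neg	L/MT	L/MT	Non-L	MTS	I
28	R/MLT	R/MT	Neg	Neg	L/LT	Non-L	FCDIIA+MTS	II
29	R/LT	Neg	Neg	L/P	L/LT	Non-L	Gliosis	I
30	R/LT	Neg	Neg	R/LT	R/LT	Non-L	Gliosis	I
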