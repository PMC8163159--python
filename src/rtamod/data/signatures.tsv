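ref_base	requires_rta	dominant_mismatch_targets	intensity_class	modification_codes	provenance
A	yes	G,T	any	m1A	curated
A	no	G	any	I	curated
A	yes	G	any	m1I	curated
A	yes	-	any	t6A,i6A,ms2i6A,m6t6A	curated
G	yes	T,A,C	any	m1G,m2G,m22G	curated
G	yes	-	weak	Gm	curated
G	no	A	any	m1G	curated
C	yes	T,A,G	any	m3C	curated
C	yes	-	weak	Cm	curated
T	optional	C,A,G	weak	D	curated
T	yes	-	weak	D	curated
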