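sprinzl_label	ref_base	known_modifications	provenance
9	G	m1G	catalogue
10	G	m2G,m22G	catalogue
20	T	D	catalogue
20	C	m3C,Cm	catalogue
20a	T	D	catalogue
26	G	m2G,m22G	catalogue
32	C	Cm,m3C	catalogue
34	A	I	catalogue
34	G	Gm	catalogue
37	G	m1G,m2G,Gm	catalogue
37	A	t6A,i6A,ms2i6A,m6t6A	catalogue
46	G	m1G	catalogue
47	T	D	catalogue
58	A	m1A	catalogue
60	A	m1A	catalogue
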