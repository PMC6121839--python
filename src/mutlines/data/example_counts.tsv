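# Per-line single-base mutation counts from a published 10-line x 5-generation
# short-term MA experiment in Chironomus riparius (worked example).  Per-line
# ts/tv columns exclude alternative alleles at multi-allelic sites; the
# experiment-wide spectrum classified 15 transitions and 11 transversions.
line_id	callable_sites	mutations	snms	alt_snm_sites	insertions	deletions	ts	tv
A1	113428649	7	2	0	3	2	1	1
A2	126279134	4	2	1	1	1	1	0
A3	125198906	3	1	0	0	2	1	0
A4	119583116	7	4	0	2	1	2	2
A5	100483488	9	4	0	2	3	0	4
A6	129246425	4	2	0	0	2	0	2
A7	127455137	3	1	1	0	2	0	0
A8	128191107	7	4	0	0	3	2	2
A9	130004076	3	2	0	0	1	2	0
A10	129317412	4	4	0	0	0	4	0
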