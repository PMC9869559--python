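id	equation	lb	ub	gene_rule	subsystem
EX_src	1 m1_c <->	-10	0		EXCHANGE
EX_snk	1 m6_c ->	0	1000		EXCHANGE
B1	1 m1_c <-> 1 m2_c	-1000	1000		SYNTHETIC
B2	1 m2_c <-> 1 m3_c	-1000	1000		SYNTHETIC
B3	1 m3_c -> 1 m4_c	0	1000		SYNTHETIC
B4	1 m4_c -> 1 m5_c	0	1000		SYNTHETIC
B5	1 m5_c -> 1 m6_c	0	1000		SYNTHETIC
R1	1 m2_c + 1 m6_c -> 2 m4_c	0	1000		SYNTHETIC
R2	2 m3_c -> 1 m2_c + 1 m1_c	0	1000		SYNTHETIC
R3	1 m4_c + 1 m2_c -> 2 m6_c	0	1000		SYNTHETIC
R4	1 m2_c + 1 m4_c <-> 2 m1_c	-1000	1000		SYNTHETIC
R5	1 m2_c + 1 m5_c <-> 2 m3_c	-1000	1000		SYNTHETIC
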