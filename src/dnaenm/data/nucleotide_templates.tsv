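# Idealized B-form nucleotide heavy-atom templates (synthetic),
# standard base reference frame; generated by scripts/make_templates.py
base	name	element	x	y	z
A	P	P	-3.1011	6.7983	-2.0631
A	OP1	O	-4.3581	6.7158	-2.8495
A	OP2	O	-2.4276	5.5448	-1.6386
A	O5'	O	-3.4130	7.6445	-0.7476
A	C5'	C	-2.8276	7.2749	0.5151
A	C4'	C	-3.8494	6.5913	1.3918
A	O4'	O	-2.5044	6.1065	1.1989
A	C3'	C	-4.7463	5.5900	0.6655
A	O3'	O	-6.0585	5.0404	0.6983
A	C2'	C	-3.7504	4.5346	0.1963
A	C1'	C	-2.4790	5.3460	0.0000
A	N9	N	-1.2890	4.5510	0.0000
A	C8	C	-0.0012	5.0116	0.0000
A	N7	N	0.8724	4.0255	0.0000
A	C5	C	0.1052	2.8760	0.0000
A	C4	C	-1.2453	3.1856	0.0000
A	N3	N	-2.2788	2.3281	0.0000
A	C2	C	-1.8391	1.0530	0.0000
A	N1	N	-0.5648	0.6021	0.0000
A	C6	C	0.4371	1.5109	0.0000
A	N6	N	1.7464	1.0456	0.0000
C	P	P	-3.1011	6.7983	-2.0631
C	OP1	O	-4.3581	6.7158	-2.8495
C	OP2	O	-2.4276	5.5448	-1.6386
C	O5'	O	-3.4130	7.6445	-0.7476
C	C5'	C	-2.8276	7.2749	0.5151
C	C4'	C	-3.8494	6.5913	1.3918
C	O4'	O	-2.5044	6.1065	1.1989
C	C3'	C	-4.7463	5.5900	0.6655
C	O3'	O	-6.0585	5.0404	0.6983
C	C2'	C	-3.7504	4.5346	0.1963
C	C1'	C	-2.4790	5.3460	0.0000
C	N1	N	-1.2890	4.5510	0.0000
C	C6	C	-0.0662	5.1785	0.0000
C	C5	C	1.0649	4.4765	0.0000
C	C4	C	0.9086	3.0092	0.0000
C	N4	N	2.0197	2.2112	0.0000
C	N3	N	-0.2413	2.4128	0.0000
C	C2	C	-1.3993	3.1555	0.0000
C	O2	O	-2.4971	2.6028	0.0000
G	P	P	-3.1011	6.7983	-2.0631
G	OP1	O	-4.3581	6.7158	-2.8495
G	OP2	O	-2.4276	5.5448	-1.6386
G	O5'	O	-3.4130	7.6445	-0.7476
G	C5'	C	-2.8276	7.2749	0.5151
G	C4'	C	-3.8494	6.5913	1.3918
G	O4'	O	-2.5044	6.1065	1.1989
G	C3'	C	-4.7463	5.5900	0.6655
G	O3'	O	-6.0585	5.0404	0.6983
G	C2'	C	-3.7504	4.5346	0.1963
G	C1'	C	-2.4790	5.3460	0.0000
G	N9	N	-1.2890	4.5510	0.0000
G	C8	C	0.0006	5.0147	0.0000
G	N7	N	0.8790	4.0312	0.0000
G	C5	C	0.1127	2.8923	0.0000
G	C4	C	-1.2320	3.1883	0.0000
G	N3	N	-2.2827	2.3335	0.0000
G	C2	C	-1.9221	1.0784	0.0000
G	N2	N	-2.8662	0.1034	0.0000
G	N1	N	-0.6087	0.6530	0.0000
G	C6	C	0.4941	1.4972	0.0000
G	O6	O	1.6419	1.0636	0.0000
T	P	P	-3.1011	6.7983	-2.0631
T	OP1	O	-4.3581	6.7158	-2.8495
T	OP2	O	-2.4276	5.5448	-1.6386
T	O5'	O	-3.4130	7.6445	-0.7476
T	C5'	C	-2.8276	7.2749	0.5151
T	C4'	C	-3.8494	6.5913	1.3918
T	O4'	O	-2.5044	6.1065	1.1989
T	C3'	C	-4.7463	5.5900	0.6655
T	O3'	O	-6.0585	5.0404	0.6983
T	C2'	C	-3.7504	4.5346	0.1963
T	C1'	C	-2.4790	5.3460	0.0000
T	N1	N	-1.2890	4.5510	0.0000
T	C6	C	-0.0666	5.1907	0.0000
T	C5	C	1.0938	4.5238	0.0000
T	C7	C	2.4401	5.1689	0.0000
T	C4	C	1.0429	3.0427	0.0000
T	O4	O	2.0612	2.3595	0.0000
T	N3	N	-0.2037	2.4879	0.0000
T	C2	C	-1.3937	3.1663	0.0000
T	O2	O	-2.4552	2.5474	0.0000
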