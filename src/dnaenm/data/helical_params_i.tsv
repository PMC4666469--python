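# Dinucleotide base-step and base-pair helical parameters, set (i)
# (in vitro experiment + X-ray crystal structure analysis compilation).
# step rows: name shift slide rise tilt roll twist   [A, A, A, deg, deg, deg]
# pair rows: name shear stretch stagger buckle propeller opening [A, A, A, deg, deg, deg]
kind	name	p1	p2	p3	p4	p5	p6
step	AA	-0.05	-0.21	3.27	-1.84	0.76	35.31
step	AT	0.00	-0.56	3.39	0.00	-1.39	31.21
step	AC	0.21	-0.54	3.39	-0.64	-1.39	31.52
step	AG	0.12	-0.27	3.38	-1.48	3.15	33.05
step	TA	0.00	0.03	3.34	0.00	5.25	36.20
step	TT	0.05	-0.21	3.27	1.84	0.76	35.31
step	TC	0.27	-0.03	3.35	1.52	3.87	34.80
step	TG	0.16	0.18	3.38	0.05	5.95	35.02
step	CA	-0.27	-0.03	3.35	-1.52	3.87	34.80
step	CT	-0.12	-0.27	3.38	1.48	3.15	33.05
step	CC	0.02	-0.47	3.28	0.40	3.86	33.17
step	CG	0.00	0.57	3.49	0.00	4.29	35.30
step	GA	-0.27	-0.03	3.35	-1.52	3.87	34.80
step	GT	-0.21	-0.54	3.39	0.64	0.91	31.52
step	GC	0.00	-0.07	3.38	0.00	0.67	34.38
step	GG	-0.02	-0.47	3.28	-0.40	3.86	33.17
pair	A-T	0.07	-0.19	0.07	1.80	-15.00	1.50
pair	T-A	-0.07	-0.19	0.07	-1.80	-15.00	1.50
pair	C-G	0.16	-0.17	0.15	-4.90	-8.70	-0.60
pair	G-C	-0.16	-0.17	0.15	4.90	-8.70	-0.60
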