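query_id	q_cluster	subject_id	s_cluster	q_start	q_end	s_start	s_end	q_aln	s_aln	probability	rmsd	tm_score	identity	q_scop	s_scop
d1g3qa_	1	d3lz6a_	1	10	44	5	39	AAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAA	AAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAA	81.7	2.89	0.25	14.0	c.37.1.10	c.2.1.2
d1wa5a_	2	d2dfda1	2	12	113	3	104	AAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAA	AAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAA	81.7	2.89	0.25	14.0	c.37.1.8	c.2.1.5
d2g0ta1	2	d2yv1a1	1	8	38	11	41	AAAAAAAAAAAAAAAAAAAAAAAAAAAAAA	AAAAAAAAAAAAAAAAAAAAAAAAAAAAAA	75.0	2.5	0.2	22.0	c.37.1.10	c.2.1.4
d2g0ta1	13	d2yv1a1	1	40	68	44	72	AAAAAAAAAAAAAAAAAAAAAAAAAAAA	AAAAAAAAAAAAAAAAAAAAAAAAAAAA	72.0	2.1	0.22	18.0	c.37.1.10	c.2.1.4
d3oqpa_	1	d1t1ra2	1	2	31	6	35	AAAAAAAAAAAAAAAAAAAAAAAAAAAAA	AAAAAAAAAAAAAAAAAAAAAAAAAAAAA	88.0	1.9	0.1	30.0	c.2.1.1	c.2.1.3
d3lz6a_	1	d2dfda1	2	0	40	2	42	AAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAA	AAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAA	90.0	1.2	0.15	35.0	c.2.1.2	c.2.1.5
d1t1ra2	1	d2yv1a1	1	7	32	9	34	AAAAAAAAAAAAAAAAAAAAAAAAA	AAAAAAAAAAAAAAAAAAAAAAAAA	71.5	2.9	0.29	12.0	c.2.1.3	c.2.1.4
d2yv1a1	1	d2g0ta1	2	3	23	5	25	AAAAAAAAAAAAAAAAAAAA	AAAAAAAAAAAAAAAAAAAA	70.0	2.0	0.2	16.0	c.2.1.4	c.37.1.10
d3lz6a_	1	d1t1ra2	1	4	34	8	38	AAAAAAAAAAAAAAAAAAAAAAAAAAAAAA	AAAAAAAAAAAAAAAAAAAAAAAAAAAAAA	85.0	3.0	0.25	20.0	c.2.1.2	c.2.1.3
d2dfda1	2	d1t1ra2	1	20	29	22	31	AAAAAAAAA	AAAAAAAAA	80.0	1.5	0.2	25.0	c.2.1.5	c.2.1.3
d2dfda1	2	d2yv1a1	1	9	44	12	47	AAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAA	AAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAA	80.0	2.0	0.3	19.0	c.2.1.5	c.2.1.4
d1t1ra2	1	d3lz6a_	1	15	37	18	40	AAAAAAAAAAAAAAAAAAAAAA	AAAAAAAAAAAAAAAAAAAAAA	99.0	0.9	0.55	40.0	c.2.1.3	c.2.1.2
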