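id	gender	age	height	mass	measured_mass	measured_mass_sd	trials_0.8	trials_1.2	trials_1.6
1	male	25	1.87	101			NA	6, 7, 8	NA
11	male	22	1.85	80			9	10	11
4	male	30	1.76	74			12, 15	13	14
7	female	29	1.72	64.5	64.5	0.8	16	17	18
8	male	20	1.57	74.9	74.9	0.9	19	20	21
9	male	20	1.69	67	67	2	25	26	27
5	male	23	1.73	71.2	71.2	0.9	32	31	33
6	male	26	1.77	86.8	86.8	0.6	40	41	42
3	female	32	1.62	54	54	2	46	47	48
12	male	22	1.85	74.2	74.2	0.5	49	50	51
13	female	21	1.70	58	58	2	55	56	57
10	male	19	1.77	92	92	2	61	62	63
15	male	22	1.83	80.5	80.5	0.8	67	68	69
17	male	23	1.86	88.3	88.3	0.8	73	74	75
16	female	28	1.69	56.2	56.2	0.6	76	77	78
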