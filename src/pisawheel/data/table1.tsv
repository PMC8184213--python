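# Assigned 15N CS (ppm) and 15N-1H DC (kHz) of the transmembrane region of
# monomeric phospholamban (PLN) and Ser16-phosphorylated PLN (pPLN), free in
# flipped bicelles or bound to SERCA in the E2 (Ca2+-free) and E1 (Ca2+-bound)
# states.  '-' = unassigned/absent; '*' = overlapped resonance (shared values).
res	PLN_cs	PLN_dc	pPLN_cs	pPLN_dc	PLN_SERCA_E2_cs	PLN_SERCA_E2_dc	pPLN_SERCA_E2_cs	pPLN_SERCA_E2_dc	PLN_SERCA_E1_cs	PLN_SERCA_E1_dc	pPLN_SERCA_E1_cs	pPLN_SERCA_E1_dc
N27	117.6*	1.19*	118.1	0.90	-	-	-	-	-	-	-	-
N30	117.6*	1.19*	121.5	3.10	-	-	-	-	-	-	-	-
L31	152.8	0.94	155.2	0.74	-	-	164.3	1.26	-	-	-	-
F32	167.7	2.46	177.9	3.38	-	-	187.6	4.07	181.6	3.78	186.6	4.56
N34	125.8	1.36	132.4	2.71	-	-	-	-	-	-	-	-
F35	164.7	1.17	166.2*	1.36*	-	-	179.1	2.86	176.4	2.30	-	-
A36	176.5	4.74	184.3	5.28	186.5	5.72	191.0	6.37	190.4	5.91	192.8	6.76
L37	123.9	4.89	132.2	5.71	136.5	6.66	146.0	6.57	146.1	4.73	151.7	5.87
I38	140.8	1.03	146.5	1.40	156.9	1.86	160.3	2.54	156.4	2.11	164.9	2.14
L39	181.7*	2.31*	185.7*	2.86*	190.3	3.88	194.4	3.99	194.5	3.76	198.5	4.75
I40	155.7	6.19	163.5*	6.88*	164.0	7.04	171.5	6.87	166.7	6.99	169.9	7.25
F41	127.8	3.39	134.6	4.19	-	-	150.0	4.46	-	-	148.4	4.33
L42	160.5	0.91	166.2*	1.36*	175.5	1.74	179.1	2.86	-	-	181.1	2.63
L43	187.5*	4.17*	190.9*	4.46*	192.8	5.77	198.3	5.76	196.5	5.89	-	-
L44	138.0	6.02	145.6	6.19	149.9	6.22	155.5	6.26	156.0	5.19	155.1	6.65
I45	139.2	1.80	144.5	2.64	152.7	2.74	160.3	2.54	-	-	162.1	3.57
A46	181.7*	2.31*	185.7*	2.86*	-	-	191.4	2.84	-	-	-	-
I47	170.5	6.35	175.9	6.65	-	-	181.8	7.23	179.5	6.74	181.9	7.99
I48	132.7	4.88	139.2	5.39	145.5	5.16	154.3	6.03	151.2	4.94	-	-
V49	157.1	1.75	160.1	2.26	-	-	-	-	-	-	-	-
M50	187.5*	4.17*	190.9*	4.46*	-	-	198.0	5.14	202.5	4.80	199.9	5.94
L51	158.3	7.06	163.5*	6.88*	-	-	-	-	-	-	-	-
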