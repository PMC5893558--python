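snp	chrom	pos	p_trait1	p_trait2	cfdr_1g2	cfdr_2g1	conjfdr	significant	lead
rs0001733	10	480000	2.75665e-05	4.73992e-08	0.000163102	3.08095e-07	0.000163102	True	False
rs0001816	10	895000	2.03299e-15	6.12968e-22	2.06203e-14	1.99215e-20	2.06203e-14	True	True
rs0001943	11	620000	2.23923e-06	6.7721e-05	1.44532e-05	0.000314419	0.000314419	True	True
rs0002248	13	330000	1.37245e-16	6.91711e-11	1.94888e-15	6.42303e-10	6.42303e-10	True	True
rs0002482	14	590000	5.00801e-16	0.00036167	5.92614e-15	0.00146928	0.00146928	True	False
rs0002495	14	655000	2.46768e-09	1.36351e-06	1.94673e-08	7.38565e-06	7.38565e-06	True	True
rs0002579	15	165000	0.00373582	1.75741e-05	0.0165777	8.78707e-05	0.0165777	True	True
rs0002821	16	465000	7.87175e-18	5.99292e-19	1.39724e-16	9.7385e-18	1.39724e-16	True	True
rs0002999	17	445000	0.00312836	6.20407e-09	0.0148076	5.04081e-08	0.0148076	True	True
rs0000186	2	20000	4.87657e-39	1.87141e-16	3.46237e-37	2.43283e-15	2.43283e-15	True	True
rs0003823	22	20000	0.004698	4.56066e-11	0.0196211	4.94072e-10	0.0196211	True	True
rs0000398	3	170000	2.14624e-09	3.1164e-20	1.90479e-08	6.75221e-19	1.90479e-08	True	True
rs0000980	6	350000	0.00892252	2.2826e-07	0.0351944	1.34881e-06	0.0351944	True	False
rs0001040	6	650000	1.27254e-21	0.00752145	4.51752e-20	0.0271608	0.0271608	True	True
rs0001180	7	445000	0.0020159	0.00147241	0.0102235	0.0056298	0.0102235	True	False
rs0001185	7	470000	2.57501e-08	0.000308661	1.82826e-07	0.00133753	0.00133753	True	True
rs0001256	7	825000	0.00117822	1.14592e-08	0.00643491	8.2761e-08	0.00643491	True	False
rs0001352	8	395000	1.43438e-19	2.03882e-26	3.3947e-18	1.32523e-24	3.3947e-18	True	True
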