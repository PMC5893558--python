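rsid	gene	chrom	pos	ref_allele	alt_allele	conjfdr	distance_bp	intergenic	p_trait1	p_trait2
rs0001816	NA	10	895000	G	T	2.06203e-14	NA	NA	2.03299e-15	6.12968e-22
rs0001943	NA	11	620000	A	C	0.000314419	NA	NA	2.23923e-06	6.7721e-05
rs0002248	NA	13	330000	A	G	6.42303e-10	NA	NA	1.37245e-16	6.91711e-11
rs0002495	NA	14	655000	T	C	7.38565e-06	NA	NA	2.46768e-09	1.36351e-06
rs0002579	NA	15	165000	C	T	0.0165777	NA	NA	0.00373582	1.75741e-05
rs0002821	NA	16	465000	A	G	1.39724e-16	NA	NA	7.87175e-18	5.99292e-19
rs0002999	GENE_E	17	445000	A	G	0.0148076	-245000	True	0.00312836	6.20407e-09
rs0000186	GENE_C	2	20000	A	C	2.43283e-15	0	False	4.87657e-39	1.87141e-16
rs0003823	NA	22	20000	C	A	0.0196211	NA	NA	0.004698	4.56066e-11
rs0000398	GENE_D	3	170000	T	C	1.90479e-08	-50000	True	2.14624e-09	3.1164e-20
rs0001040	NA	6	650000	A	G	0.0271608	NA	NA	1.27254e-21	0.00752145
rs0001185	NA	7	470000	A	C	0.00133753	NA	NA	2.57501e-08	0.000308661
rs0001352	NA	8	395000	G	A	3.3947e-18	NA	NA	1.43438e-19	2.03882e-26
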