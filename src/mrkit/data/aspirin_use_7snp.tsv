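SNP	chrom_pos	effect_allele	other_allele	eaf	beta	se	pval	n
rs10455872	6: 161010118	G	NA	0.0810412	0.0133593	0.00150604	7.31E-19	337159
rs117733303	6: 160922870	G	NA	0.0186833	0.0196617	0.00303468	9.25E-11	337159
rs1831733	9: 22076071	C	NA	0.475704	0.00723124	0.000826446	2.15E-18	337159
rs2521501	15: 91437388	T	NA	0.322313	0.00490502	0.00088581	3.07E-08	337159
rs583104	1: 109821307	G	NA	0.42184	-0.00486719	0.00084236	7.56E-09	337159
rs73015016	19: 11191300	T	NA	0.773202	0.00622211	0.00098108	2.27E-10	337159
rs7412	19: 45412079	A	NA	0.118872	-0.00726876	0.00126954	1.03E-08	337159
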