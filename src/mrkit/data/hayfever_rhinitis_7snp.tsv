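SNP	chrom_pos	effect_allele	other_allele	eaf	beta	se	pval	n
rs10455872	6: 161010118	G	NA	0.0810412	-0.00682856	0.00376191	0.0694992	83529
rs117733303	6: 160922870	G	NA	0.0186833	-0.00807061	0.00759619	0.288032	83529
rs1831733	9: 22076071	C	NA	0.475704	-0.00302929	0.00206174	0.141758	83529
rs2521501	15: 91437388	T	NA	0.322313	-0.00294589	0.00221074	0.182687	83529
rs583104	1: 109821307	G	NA	0.42184	-0.0028417	0.00210676	0.177388	83529
rs73015016	19: 11191300	T	NA	0.773202	-0.00137204	0.00245182	0.575751	83529
rs7412	19: 45412079	A	NA	0.118872	0.000856574	0.00317097	0.78706	83529
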