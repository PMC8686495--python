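smr_label	snp_id	p_smr	p_adj	gene_name
Meta_GENE_Blood	rs8042849	9.17e-09	0.0004	PSMA4
Meta_EXON_Blood	rs931794	1.06e-07	0.0029	PSMA4
Meta_EXON_Blood	rs8042849	2.44e-08	0.0013	PSMA4
BBJ_GTEx_Blood	rs9274510	5.70e-07	0.0106	HLA-DQB1
BBJ_GENE_Blood	rs147560086	2.26e-08	0.0010	RAD52
BBJ_GENE_Blood	rs8042849	7.81e-08	0.0017	PSMA4
BBJ_EXON_Blood	rs31487	1.96e-08	0.0011	CLPTM1L
BBJ_EXON_Blood	rs147560086	2.77e-08	0.0012	RAD52
BBJ_EXON_Blood	rs12592111	2.40e-06	0.0288	IREB2
BBJ_EXON_Blood	rs8042849	1.66e-07	0.0040	PSMA4
BBJ_EXON_Blood	rs12822733	1.74e-07	0.0037	RAD52
BBJ_EXON_Blood	rs931794	2.70e-10	4.53e-05	PSMA4
BBJ_EXON_Blood	rs402710	9.79e-09	0.0008	CLPTM1L
BBJ_EXON_Blood	rs9274564	5.15e-07	0.0072	HLA-DQB1
BBJ_EXON_Blood	rs9274564	5.14e-07	0.0079	HLA-DRB9
BBJ_EXON_Blood	rs28755305	9.50e-07	0.0123	HLA-DQB2
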