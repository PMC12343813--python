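snp_id	effect_allele	other_allele	weight	freq
SNP_1	A	G	0.10	0.30
SNP_2	A	G	0.12	0.40
SNP_3	A	G	-0.08	0.50
SNP_4	A	G	0.05	0.25
SNP_5	A	G	0.20	0.60
SNP_6	A	G	-0.15	0.35
SNP_7	A	G	0.07	0.45
SNP_8	A	G	0.11	0.55
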