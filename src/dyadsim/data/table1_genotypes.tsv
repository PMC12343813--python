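individual_id	SNP_1	SNP_2	SNP_3	SNP_4	SNP_5	SNP_6	SNP_7	SNP_8
parent	0	1	1	2	1	2	2	1
child	1	1	2	2	0	1	1	1
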