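dyad_id,person_a_id,person_b_id,dyad_type,child_sex
table1,parent,child,mother_child,male
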