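group	n_samples	n_subgroup3
posterior_only	36	NA
anterior_only	27	NA
pan	35	14
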