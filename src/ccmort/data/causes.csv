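cause,deaths,deaths_ne_regions
all_cause,14931,
all_cancer,1092,
cns,303,82
lymphoid_leukaemia,180,
myeloid_leukaemia,92,
nhl,53,
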