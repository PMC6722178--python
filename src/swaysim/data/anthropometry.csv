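segment,mass_fraction,com_fraction
foot,0.029,0.500
shank,0.093,0.433
thigh,0.200,0.433
head_arms_trunk,0.678,0.626
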