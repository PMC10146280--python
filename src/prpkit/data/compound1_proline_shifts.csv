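residue,delta_c_beta,delta_c_gamma
ProI,30.33,25.94
ProII,29.41,25.87
ProIII,30.29,25.90
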