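unit,Y_ac,Y_bu,Y_pr
cow1,1.38e-06,1.73e-07,2.37e-06
cow2,1.52e-06,1.55e-07,2.16e-06
cow3,1.43e-06,1.5e-07,2.64e-06
cow4,1.39e-06,1.83e-07,2.54e-06
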