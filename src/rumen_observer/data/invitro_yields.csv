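unit,Y_ac,Y_bu,Y_pr
inoculum1_grass,1.9e-07,7.7e-08,9.3e-07
inoculum2_grass,1.7e-07,2.6e-08,1.4e-07
inoculum1_hay,7e-08,3e-08,2.9e-07
inoculum2_hay,1.1e-07,2.2e-08,2.3e-07
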