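unit,acetate,butyrate,propionate
inoculum1_grass,7.1,11.8,13.2
inoculum2_grass,4.6,7.8,1.3
inoculum1_hay,16.9,20.0,25.6
inoculum2_hay,10.5,16.4,18.0
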