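unit,acetate,butyrate,propionate
cow1,10.1,10.2,14.7
cow2,15.4,14.1,17.1
cow3,16.5,18.4,25.9
cow4,23.8,20.5,21.3
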