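unit,acetate,butyrate,propionate
cow1,2.9,3.4,8.3
cow2,1.8,2.8,5.7
cow3,3.6,4.6,10.9
cow4,4.2,4.5,10.5
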