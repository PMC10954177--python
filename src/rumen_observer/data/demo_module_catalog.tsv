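module_id	ko_id
M00579	K00625
M00579	K00925
M99999	K00634
M99999	K00929
M99999	K01034
M00013	K01847
M00013	K11264
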