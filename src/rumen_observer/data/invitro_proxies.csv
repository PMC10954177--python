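unit,time_h,m_ac,m_bu,m_pr
inoculum1_grass,2,33139,52574,3503
inoculum1_grass,4,37601,57719,3669
inoculum1_grass,8,60680,116469,8181
inoculum1_grass,24,70338,109282,8971
inoculum1_hay,2,14487,18600,640
inoculum1_hay,4,42303,61808,4323
inoculum1_hay,8,36663,49934,3673
inoculum1_hay,24,82646,118876,13470
inoculum2_grass,2,87093,184833,23114
inoculum2_grass,4,91845,206660,27944
inoculum2_grass,8,105360,227768,24257
inoculum2_grass,24,83174,235760,36697
inoculum2_hay,2,111166,240822,31287
inoculum2_hay,4,106780,240218,31758
inoculum2_hay,8,101168,194157,22945
inoculum2_hay,24,102789,218833,22005
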