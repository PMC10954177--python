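unit,time_h,m_ac,m_bu,m_pr
cow1,7,47708,76650,7229
cow1,10,45126,72740,6963
cow1,13,55602,92161,10052
cow1,16,57647,95845,9955
cow1,19,64097,108538,11753
cow1,22,56031,89023,8104
cow1,25,54965,90047,8651
cow1,28,65061,108791,11608
cow1,31,54497,90950,9396
cow1,34,69391,117048,12755
cow1,37,57204,94074,10278
cow1,40,67378,115549,13197
cow1,43,63766,109147,11730
cow1,46,67489,112391,11249
cow1,49,57861,96751,10067
cow1,52,56384,97451,11329
cow2,7,49745,80804,8064
cow2,10,48073,80864,8626
cow2,13,52536,87082,9009
cow2,16,49837,84439,8991
cow2,19,59831,98867,9808
cow2,22,58632,102169,11502
cow2,25,58376,97994,9774
cow2,28,40248,67514,6934
cow2,31,66988,113688,12201
cow2,34,69821,118291,12928
cow2,37,67276,114353,12633
cow2,40,54960,94216,10080
cow2,43,64366,110819,12292
cow2,46,50587,87848,9732
cow2,49,58103,100618,11186
cow2,52,54381,96853,10745
cow3,7,42144,73426,8149
cow3,10,48535,84226,9554
cow3,13,50274,85419,9264
cow3,16,55855,97337,11066
cow3,19,45496,78949,8440
cow3,22,58116,102467,11366
cow3,25,49365,80924,7839
cow3,28,54277,93929,10324
cow3,31,52852,89409,9596
cow3,34,66731,111399,11580
cow3,37,60735,102816,11227
cow3,40,53184,90607,10341
cow3,43,54231,92020,9335
cow3,46,65121,110914,11322
cow3,49,49727,84625,9163
cow3,52,51256,91281,10974
cow4,7,46298,77495,8128
cow4,10,12944,24482,2847
cow4,13,58665,99615,10811
cow4,16,60244,100443,10838
cow4,19,54556,90413,9539
cow4,22,55437,95868,10574
cow4,25,53430,86833,8927
cow4,28,54539,90640,9399
cow4,31,60154,103506,12079
cow4,34,64751,114801,13578
cow4,37,56813,93832,10265
cow4,40,56088,93850,9756
cow4,43,58200,101479,11216
cow4,46,53288,89818,9414
cow4,49,52679,91936,10771
cow4,52,57640,98357,11167
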