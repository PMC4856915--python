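polymer_id,wu_eq_percent,sd_percent
poly(DTB adipate),18.2,1.2
poly(DTB succinate),4.0,0.3
poly(DTBn adipate),32.2,7.2
poly(DTE adipate),36.2,3.2
poly(DTE glutarate),29.6,3.4
poly(DTiP adipate),27.6,1.0
poly(DTM adipate),14.5,3.5
poly(DTM sebacate),12.3,2.7
poly(DTO adipate),6.1,0.3
poly(DTO sebacate),2.7,0.4
poly(DTO succinate),3.5,0.6
poly(HTE adipate),7.8,1.1
poly(HTE succinate),43.1,10.6
poly(HTH adipate),18.0,2.1
poly(HTH sebacate),2.3,0.4
poly(DTM R(+) methyladipate),90.1,8.8
poly(DTsB R(+) glutarate),97.4,4.1
poly(DTsB R(+) methyladipate),136.5,10.0
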