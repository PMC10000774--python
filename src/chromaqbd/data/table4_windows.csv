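cma,lsl,usl
RS1,1.2,12
RS2,1.2,12
RT_CMN,2,7
RT_DMCMN,2,7
RT_BDMCMN,2,7
TP_CMN,2000,
TP_DMCMN,2000,
TP_BDMCMN,2000,
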