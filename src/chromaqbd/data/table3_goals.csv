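cma,upper_limit,lower_limit,goal,predicted,experimental
RS1,2.12,0.85,>1.2,1.87,2.05
RS2,2.04,0.83,>1.2,1.77,1.88
RT_CMN,6.51,2.38,Maximize,4.65,4.86
RT_DMCMN,7.18,2.51,In range,5.47,5.36
RT_BDMCMN,7.9,2.66,Minimize,6.02,5.93
TP_CMN,5800,655,>2000,4818,5122
TP_DMCMN,4644,679,>2000,3937,4144
TP_BDMCMN,3699,2637,>2000,4905,5249
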