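source,analyte,mean_a,sd_a,n_a,mean_b,sd_b,n_b,t_printed,f_printed
Solgar,Curcumin,27.15,0.35,3,27.62,0.26,3,1.87,1.76
Solgar,Demethoxycurcumin,15.6,0.24,3,15.86,0.15,3,1.02,2.67
Solgar,Bisdemethoxycurcumin,3.78,0.17,3,3.80,0.18,3,0.11,1.05
Longvida,Curcumin,21.84,0.03,3,21.86,0.08,3,0.309,5.37
Longvida,Demethoxycurcumin,13.6,0.12,3,13.62,0.11,3,0.241,1.11
Longvida,Bisdemethoxycurcumin,3.36,0.07,3,3.36,0.06,3,0.341,1.31
EthanolExtract,Curcumin,31.71,0.60,3,31.54,0.09,3,2.62,1.83
EthanolExtract,Demethoxycurcumin,9.81,0.13,3,9.84,0.14,3,0.322,1.21
EthanolExtract,Bisdemethoxycurcumin,3.84,0.15,3,3.77,0.25,3,0.372,2.59
AcetoneExtract,Curcumin,20.28,0.17,3,20.40,0.44,3,0.454,6.37
AcetoneExtract,Demethoxycurcumin,8.37,0.15,3,8.52,0.36,3,0.659,5.09
AcetoneExtract,Bisdemethoxycurcumin,3.97,0.12,3,3.96,0.10,3,0.175,1.31
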