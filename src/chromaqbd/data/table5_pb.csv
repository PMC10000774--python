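run,pH,ACN,Temperature,Buffer,RS1,RS2,RT_BDMCMN,RT_DMCMN,RT_CMN,TP_BDMCMN,TP_DMCMN,TP_CMN
1,2.5,54,35,8,1.84,1.729,4.878,5.373,5.919,4806,3970,4915
2,2.9,54,35,12,1.84,1.728,4.88,5.374,5.923,4808,3966,4919
3,2.9,54,35,12,1.84,1.728,4.88,5.374,5.924,4809,3965,4920
4,2.9,57,32,8,1.834,1.719,4.877,5.368,5.918,4805,3968,4918
5,2.9,57,35,8,1.836,1.722,4.875,5.369,5.917,4801,3965,4911
6,2.5,54,32,8,1.838,1.726,4.88,5.374,5.92,4810,3973,4920
7,2.5,57,32,12,1.836,1.721,4.877,5.369,5.916,4805,3967,4909
8,2.5,54,32,12,1.839,1.726,4.881,5.374,5.921,4811,3974,4917
9,2.5,57,35,8,1.837,1.724,4.874,5.368,5.914,4800,3964,4908
10,2.9,57,32,12,1.835,1.72,4.878,5.37,5.919,4806,3969,4913
11,2.9,54,32,8,1.836,1.724,4.881,5.375,5.923,4811,3968,4919
12,2.5,57,35,12,1.838,1.725,4.875,5.368,5.915,4801,3965,4909
13,2.7,55.5,33.5,10,1.836,1.721,4.874,5.374,5.915,4813,3977,4916
14,2.7,55.5,33.5,10,1.833,1.726,4.879,5.369,5.921,4807,3971,4923
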