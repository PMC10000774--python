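analyte,linearity_low,linearity_high,slope,intercept,r2,lod,loq
Curcumin,0.76,24.5,2222250,499471.1,0.9997,0.024,0.075
Demethoxycurcumin,0.51,10.0,3457396,-414324.79,0.9997,0.0105,0.319
Bisdemethoxycurcumin,0.13,4.3,1077486.9,-133404.51,0.9986,0.335,1.015
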