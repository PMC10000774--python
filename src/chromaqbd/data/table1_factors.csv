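name,low,medium,high,units
pH,2.5,3,3.5,
ACN,50,60,70,%
Temperature,25,30,35,degC
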