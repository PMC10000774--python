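name,low,high,units
ACN,54,57,%
pH,2.5,2.9,
Temperature,32,35,degC
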