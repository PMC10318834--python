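dimension,level,decrement
mo,1,0.0
mo,2,0.066
mo,3,0.095
mo,4,0.246
mo,5,0.334
sc,1,0.0
sc,2,0.059
sc,3,0.091
sc,4,0.199
sc,5,0.257
ua,1,0.0
ua,2,0.051
ua,3,0.074
ua,4,0.164
ua,5,0.213
pd,1,0.0
pd,2,0.050
pd,3,0.072
pd,4,0.224
pd,5,0.271
ad,1,0.0
ad,2,0.043
ad,3,0.069
ad,4,0.211
ad,5,0.316
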