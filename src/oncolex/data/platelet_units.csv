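unit,factor
10^9/L,1
K/uL,1
K/cmm,1
x10E3/uL,1
/uL,0.001
/nL,1
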