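# Vitis vinifera: lowest whole-plant sieve-tube structural resistance.
R_p: 2.4e+20
W_p: 3.57e-11
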