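# Robinia pseudoacacia.
R_p: 2.3e+21
W_p: 1.37e-8
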