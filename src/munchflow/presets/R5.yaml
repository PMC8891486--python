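# Gossypium barbadense: highest structural resistance.
R_p: 8.5e+21
W_p: 1.37e-8
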