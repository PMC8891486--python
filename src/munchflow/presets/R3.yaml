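# Ricinus communis; phloem-zone volume chosen to maximize export while
# avoiding runaway viscosity under drought.
R_p: 1.1e+21
W_p: 1.04e-8
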