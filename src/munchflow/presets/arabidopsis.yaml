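# Arabidopsis thaliana: low maximum loading rate.
V_maxL: 1.30e-8
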