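# Nicotiana tabacum: intermediate maximum loading rate (model default).
V_maxL: 1.58e-7
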