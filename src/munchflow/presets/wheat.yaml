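# Triticum aestivum: high maximum loading rate.
V_maxL: 2.30e-6
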