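# Worked-example regulatory rule, 1-active variant
R7r = NOT(1R9)
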