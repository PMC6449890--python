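# Worked three-gene example used to define the sweep semantics.
g1 = g3
g2 = g1 or g3
g3 = g2
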