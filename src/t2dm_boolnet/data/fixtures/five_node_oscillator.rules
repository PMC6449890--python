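# Three-node negative-feedback ring (no fixed point) plus two reporter
# nodes; its single attractor is cyclic with fractional expression levels.
A = not C
B = A
C = B
D = A
E = not D
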