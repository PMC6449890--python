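# Four-gene positive feedback loop from the full model's stress arm, with
# the upstream sensors PERK and ATF6 left as undefined (constant FALSE)
# references. Bistable: all-ON and all-OFF attractors.
EIF2S1 = GADD34 and (not PERK)
ATF4 = EIF2S1
CHOP = ATF6 or ATF4
GADD34 = CHOP
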