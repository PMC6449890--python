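# Mapping from printed node spellings (Greek letters, hyphens, slashes,
# spacing variants) to the canonical ASCII identifiers used throughout the
# package. Longest spellings are matched first; matches never extend into
# an adjacent identifier character.
"TNF α": TNFA
"TNFα": TNFA
"TNF alpha": TNFA
"IL-6": IL6
"IKK β": IKKB
"IKKβ": IKKB
"IKK beta": IKKB
"NF κB": NFKB
"NFκB": NFKB
"NF kB": NFKB
"NF-kB": NFKB
"IKB α": IKBA
"IKBα": IKBA
"IkB alpha": IKBA
"GSK3 β": GSK3B
"GSK3β": GSK3B
"GSK3 beta": GSK3B
"PKC α": PKCA
"PKCα": PKCA
"PGC1 α": PGC1A
"PGC1α": PGC1A
"PPAR α": PPARA
"PPARα": PPARA
"TSC1/2": TSC2
"APAF-1": APAF1
"Cytochrome c": CytochromeC
"Cytochrome C": CytochromeC
"Cytochrome": CytochromeC
"Caspase-3": CASP3
"Caspase-6": CASP6
"Caspase-7": CASP7
"Caspase-8": CASP8
"Caspase-9": CASP9
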