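name,formula,charge
acetate,C2H3O2,-1
lactate,C3H5O3,-1
propionate,C3H5O2,-1
pyruvate,C3H3O3,-1
succinate,C4H4O4,-2
ethanol,C2H6O,0
glucose,C6H12O6,0
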