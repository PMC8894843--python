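# Illustrative Compound/Disease metapaths over a Hetionet-like schema.
# One metapath per line, comma-separated entity types.
# For full-scale reproduction of published experiments, supply the exact
# metapath list used there instead of these defaults.
Compound,Gene,Disease
Compound,Gene,Gene,Disease
Compound,SideEffect,Compound,Gene,Disease
Compound,PharmacologicClass,Compound,Gene,Disease
Disease,Symptom,Disease,Gene,Compound
Compound,Gene,Anatomy,Disease
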