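metabolite	kegg_compound	pathways
L-aspartic acid	C00049	ko00250:Alanine, aspartate and glutamate metabolism;ko00270:Cysteine and methionine metabolism
D/L-pyroglutamic acid	C01879	ko00480:Glutathione metabolism
calystegine B2	C10846	ko00960:Tropane, piperidine and pyridine alkaloid biosynthesis
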