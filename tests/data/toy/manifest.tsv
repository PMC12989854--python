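gene_id	expected	detail
g01	accepted	clean
g02	accepted	frame offset 1
g03	accepted	frame offset 2
g04	accepted	internal stop masked
g05	accepted	gappy codon column removed
g06	accepted	ambiguity retained
g07	accepted	clean
g08	accepted	clean
g09	accepted	clean
g10	too_few_taxa	8 taxa
g11	no_frame_found	no terminal stops
g12	low_information	invariant alignment
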