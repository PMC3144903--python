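# Allelic-discrimination (TaqMan-style) assay for the exon-29 G>A transition:
# the published PCR primers and the two probes differing at the variant base
# (GAG wild-type core vs AAG mutant core).
forward_primer: TCTGTCCGTCCGTCCCT
reverse_primer: GCCAGATGTGCTTGTCAAAGAAG
wt_probe: TGGCCGAGCTGCAG
mut_probe: TGGCCAAGCTGCAG
wt_allele: G
mut_allele: A
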