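# The five predicted haplotypes across the 37 variant sites (site order as in
# pkd1_variants.tsv) and the reported per-dog haplotype pairs. Hap1 is the background
# haplotype on which the exon-29 G>A change arose (Hap5 = Hap1 with A at the
# exon-29 slot).
#assign:	Dog1=Hap5/Hap4	Dog2=Hap5/Hap2	Dog3=Hap1/Hap2	Dog4=Hap1/Hap3
Hap1	31A-C-A-G-G-G-10C-G-G-G-T-G-GGG-G-Del-11C-C-C-T-G-C-G-T-T-G-C-T-G-10C-G-T-T-T-T-7C-C-G
Hap2	22A-C-A-G-G-A-11C-G-G-G-T-G-GGG-G-Del-13C-C-C-T-G-C-G-T-T-G-C-T-G-11C-G-T-T-T-T-7C-C-G
Hap3	22A-C-A-G-T-A-11C-G-G-G-T-G-GGG-G-Del-13C-C-C-T-G-C-G-T-T-G-C-T-G-11C-G-T-T-T-T-7C-C-G
Hap4	22A-T-G-G-G-A-11C-A-A-A-T-A-GGG-G-Del-13C-G-C-C-G-C-G-C-C-A-C-T-A-11C-G-C-C-T-C-6C-C-A
Hap5	31A-C-A-G-G-G-10C-G-G-G-T-G-GGG-G-Del-11C-C-C-T-G-C-G-T-T-G-C-T-G-10C-A-T-T-T-T-7C-C-G
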