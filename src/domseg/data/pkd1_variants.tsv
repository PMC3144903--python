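# Canine Pkd1 variant sites in two BTPKD-affected and two unaffected English
# Bull Terriers. Positions are 1-based offsets (or inclusive ranges) from the
# 5' end of the named feature. db_ref lists the reference allele(s) reported
# in public databases ("|" separates discordant database alleles; "59bp"
# marks a 59-bp segment present in the reference). The adjacent-dinucleotide
# substitution in exon 17 (AA>GC) is represented as two single-nucleotide
# rows, .1 and .2.
#status:	Dog1=affected	Dog2=affected	Dog3=unaffected	Dog4=unaffected
assay_id	feature	position	db_ref	Dog1	Dog2	Dog3	Dog4
ss316885484	5' UTR	171-192	22A	22A/31A	22A/31A	22A/31A	22A/31A
ss316885498	5' UTR	720	T	T/C	C/C	C/C	C/C
ss316885500	5' UTR	1326	G	G/A	A/A	A/A	A/A
ss316885502	Intron 4	234	G|T	G/G	G/G	G/G	G/G
ss316885504	Exon 7	122	G	G/G	G/G	G/G	G/T
ss316885506	Exon 7	206	G	G/A	G/A	G/A	G/A
ss316885508	Intron 7	110	11C	10C/11C	10C/11C	10C/11C	10C/11C
ss316885512	Intron 8	347	A|G	A/G	G/G	G/G	G/G
ss316885514	Intron 9	162	A|G	A/G	G/G	G/G	G/G
ss316885517	Intron 9	222	A|G	A/G	G/G	G/G	G/G
ss316885519	Intron 11	395	T|G	T/T	T/T	T/T	T/T
ss316885521	Exon 12	18	A|G	A/G	G/G	G/G	G/G
ss316885523	Intron 12	26-29	ACC|GGG	GGG/GGG	GGG/GGG	GGG/GGG	GGG/GGG
ss316885527	Intron 12	32	A|G	G/G	G/G	G/G	G/G
ss316885530	Intron 12	34-93	59bp	Del/Del	Del/Del	Del/Del	Del/Del
ss316885534	Intron 14	171-184	11C|13C	11C/13C	11C/13C	11C/13C	11C/13C
ss316885536	Exon 15	1235	C|G	C/G	C/C	C/C	C/C
ss316885539	Exon 15	1693	C|T	C/C	C/C	C/C	C/C
ss316885541	Intron 16	275	C|T	C/T	T/T	T/T	T/T
ss316885543.1	Exon 17	85	A|G	G/G	G/G	G/G	G/G
ss316885543.2	Exon 17	86	A|C	C/C	C/C	C/C	C/C
ss316885546	Intron 17	41	G|T	G/G	G/G	G/G	G/G
ss316885548	Exon 23	125	C	C/T	T/T	T/T	T/T
ss316885550	Exon 23	518	T	C/T	T/T	T/T	T/T
ss316885552	Intron 23	239	A	A/G	G/G	G/G	G/G
ss316885554	Exon 26	5	C|T	C/C	C/C	C/C	C/C
ss316885556	Intron 26	33	T|C	T/T	T/T	T/T	T/T
ss316885559	Intron 26	926	A|G	A/G	G/G	G/G	G/G
ss316885561	Intron 27	63-74	11C	10C/11C	10C/11C	10C/11C	10C/11C
ss316885563	Exon 29	42	G	G/A	G/A	G/G	G/G
ss316885565	Intron 30	335	C	C/T	T/T	T/T	T/T
ss316885567	Intron 30	597	C	C/T	T/T	T/T	T/T
ss316885569	Exon 31	28	G	T/T	T/T	T/T	T/T
ss316885571	Intron 37	204	C	C/T	T/T	T/T	T/T
ss316885573	Intron 41	19	6C	6C/7C	7C/7C	7C/7C	7C/7C
ss316885575	Intron 41	117	A|C	C/C	C/C	C/C	C/C
ss316885578	Intron 42	52	A	A/G	G/G	G/G	G/G
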