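# Restriction enzyme table for in-silico CAPS digestion.
# cut_offset: 0-based offset within the recognition site where the enzyme
# cuts (0 = immediately 5' of the site's first base). Only unambiguous
# ACGT recognition sites are carried; this is an editable resource, not a
# REBASE import. MboI and SphI are the enzymes used for the GBS library
# digestion in the study this package models.
name	site	cut_offset
MboI	GATC	0
SphI	GCATGC	5
EcoRI	GAATTC	1
HindIII	AAGCTT	1
TaqI	TCGA	1
AluI	AGCT	2
RsaI	GTAC	2
HaeIII	GGCC	2
MseI	TTAA	1
DraI	TTTAAA	3
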