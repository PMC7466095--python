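# Genes differentially expressed between R182 and M82 at both breaker (BR)
# and mature red (MR) fruit stages, transcribed from the published
# common-DEG table of that study. Positions are SL3.0 coordinates; in_region
# marks the genes the source table prints in bold as belonging to the
# introgressed region of R182.
gene_id	chrom	start	end	br_logfc	mr_logfc	in_region	annotation
Solyc01g073810	1	81055373	81056169	-6.154	-2.521	0	LOW QUALITY: Cysteine/Histidine-rich C1 domain family protein
Solyc01g081250	1	80365913	80367306	-4.587	-4.299	0	Glutathione s-transferase, putative
Solyc03g045140	3	11633346	11652595	10.729	5.813	0	Cyclopropane-fatty-acyl-phospholipid synthase
Solyc03g096130	3	59424648	59428566	7.654	5.344	0	Protein yippee-like
Solyc03g096250	3	59662319	59665587	4.241	4.959	0	Protein yippee-like
Solyc05g021163	5	26616597	26617138	-3.790	-3.507	0	Ubiquitin-conjugating enzyme 34
Solyc07g048040	7	59358115	59359332	2.461	3.096	1	Calcium-dependent lipid-binding domain-containing protein
Solyc07g048100	7	59411341	59428966	-5.474	-5.426	1	BRCT domain-containing protein
Solyc07g049140	7	59495183	59496455	-13.070	-13.219	1	Metallocarboxypeptidase inhibitor
Solyc07g049200	7	59621580	59624273	-2.536	-1.398	1	Coiled-coil domain-containing protein 21, putative isoform 2
Solyc07g049310	7	59686834	59695592	3.003	2.426	1	Major facilitator superfamily protein
Solyc07g062600	7	65419623	65420348	-3.908	-4.307	0	Acyl-CoA N-acyltransferase with RING/FYVE/PHD-type zinc finger protein
Solyc07g062605	7	65423519	65426708	-3.745	-4.538	0	Acyl-CoA N-acyltransferase with RING/FYVE/PHD-type zinc finger protein
Solyc09g074380	9	66596363	66601065	2.161	1.885	0	DCD (Development and Cell Death) domain protein
Solyc11g011570	11	4638263	4639371	5.913	4.566	0	RING/U-box superfamily protein
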