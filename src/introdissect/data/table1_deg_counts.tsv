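# Per-chromosome counts of up/downregulated genes between the sub-line R182
# and cv. M82 at breaker (BR) and mature red (MR) fruit stages, transcribed
# from the published DEG distribution table of that study. Chromosome 0 holds
# unanchored genes, kept as printed.
chrom	br_up	br_down	mr_up	mr_down
0	1	0	0	0
1	3	6	4	8
2	3	2	4	2
3	6	0	6	9
4	1	0	3	4
5	2	1	1	5
6	1	1	2	2
7	3	6	4	12
8	1	0	4	4
9	7	1	4	4
10	4	0	2	1
11	1	1	5	2
12	2	1	1	7
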