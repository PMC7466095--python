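##gff-version 3
# Gene model for the donor border gene Sopen07g024640 on S. pennellii
# chromosome 7. The gene span (70111740-70120667, 8928 bp) is as published;
# the internal UTR/CDS boundaries are SYNTHETIC stand-ins (the source prints
# only that the 3'UTR begins upstream of position 70119958), chosen so the
# 3'UTR covers the published recombination interval (70119958, 70120258).
Spenn-ch07	introdissect	gene	70111740	70120667	.	+	.	ID=Sopen07g024640
Spenn-ch07	introdissect	five_prime_UTR	70111740	70111959	.	+	.	ID=Sopen07g024640.five_prime_UTR.0;Parent=Sopen07g024640
Spenn-ch07	introdissect	CDS	70111960	70119099	.	+	0	ID=Sopen07g024640.CDS.1;Parent=Sopen07g024640
Spenn-ch07	introdissect	three_prime_UTR	70119100	70120667	.	+	.	ID=Sopen07g024640.three_prime_UTR.2;Parent=Sopen07g024640
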