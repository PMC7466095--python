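# Synthetic protein-similarity hit table (12-column tabular dialect) encoding
# the hit structure implied by the published homology table for the tomato
# chromosome-7 introgression sub-line R182 (see table3_relations.tsv).
# This file is constructed, not measured: scores/identities are placeholders
# arranged so that best-bidirectional-hit extraction and relationship typing
# reproduce the printed relationship column. SolycUnlisted01 is a synthetic
# placeholder id for the background partner the printed table leaves unnamed
# in the Sopen07g024590 BBH row.
Sopen07g024420	Solyc07g047990	95.0	300	15	0	1	300	1	300	1.0e-120	500.0
Solyc07g047990	Sopen07g024420	95.0	300	15	0	1	300	1	300	1.0e-120	500.0
Sopen07g024430	Solyc07g048000	95.0	300	15	0	1	300	1	300	1.0e-120	501.0
Solyc07g048000	Sopen07g024430	95.0	300	15	0	1	300	1	300	1.0e-120	501.0
Sopen07g024440	Solyc07g048010	95.0	300	15	0	1	300	1	300	1.0e-120	502.0
Solyc07g048010	Sopen07g024440	95.0	300	15	0	1	300	1	300	1.0e-120	502.0
Sopen07g024460	Solyc07g048040	95.0	300	15	0	1	300	1	300	1.0e-120	503.0
Solyc07g048040	Sopen07g024460	95.0	300	15	0	1	300	1	300	1.0e-120	503.0
Sopen07g024470	Solyc07g048050	95.0	300	15	0	1	300	1	300	1.0e-120	504.0
Solyc07g048050	Sopen07g024470	95.0	300	15	0	1	300	1	300	1.0e-120	504.0
Sopen07g024480	Solyc07g048060	95.0	300	15	0	1	300	1	300	1.0e-120	505.0
Solyc07g048060	Sopen07g024480	95.0	300	15	0	1	300	1	300	1.0e-120	505.0
Sopen07g024490	Solyc07g048070	95.0	300	15	0	1	300	1	300	1.0e-120	506.0
Solyc07g048070	Sopen07g024490	95.0	300	15	0	1	300	1	300	1.0e-120	506.0
Sopen07g024500	Solyc07g048080	95.0	300	15	0	1	300	1	300	1.0e-120	507.0
Solyc07g048080	Sopen07g024500	95.0	300	15	0	1	300	1	300	1.0e-120	507.0
Sopen07g024510	Solyc07g048090	95.0	300	15	0	1	300	1	300	1.0e-120	508.0
Solyc07g048090	Sopen07g024510	95.0	300	15	0	1	300	1	300	1.0e-120	508.0
Sopen07g024540	Solyc07g048110	95.0	300	15	0	1	300	1	300	1.0e-120	509.0
Solyc07g048110	Sopen07g024540	95.0	300	15	0	1	300	1	300	1.0e-120	509.0
Sopen07g024550	Solyc07g048120	95.0	300	15	0	1	300	1	300	1.0e-120	510.0
Solyc07g048120	Sopen07g024550	95.0	300	15	0	1	300	1	300	1.0e-120	510.0
Sopen07g025170	Solyc07g049190	95.0	300	15	0	1	300	1	300	1.0e-120	511.0
Solyc07g049190	Sopen07g025170	95.0	300	15	0	1	300	1	300	1.0e-120	511.0
Sopen07g025210	Solyc07g049200	95.0	300	15	0	1	300	1	300	1.0e-120	512.0
Solyc07g049200	Sopen07g025210	95.0	300	15	0	1	300	1	300	1.0e-120	512.0
Sopen07g025220	Solyc07g049210	95.0	300	15	0	1	300	1	300	1.0e-120	513.0
Solyc07g049210	Sopen07g025220	95.0	300	15	0	1	300	1	300	1.0e-120	513.0
Sopen07g025230	Solyc07g049220	95.0	300	15	0	1	300	1	300	1.0e-120	514.0
Solyc07g049220	Sopen07g025230	95.0	300	15	0	1	300	1	300	1.0e-120	514.0
Sopen07g025240	Solyc07g049230	95.0	300	15	0	1	300	1	300	1.0e-120	515.0
Solyc07g049230	Sopen07g025240	95.0	300	15	0	1	300	1	300	1.0e-120	515.0
Sopen07g025280	Solyc07g049250	95.0	300	15	0	1	300	1	300	1.0e-120	516.0
Solyc07g049250	Sopen07g025280	95.0	300	15	0	1	300	1	300	1.0e-120	516.0
Sopen07g024590	SolycUnlisted01	95.0	300	15	0	1	300	1	300	1.0e-120	517.0
SolycUnlisted01	Sopen07g024590	95.0	300	15	0	1	300	1	300	1.0e-120	517.0
Sopen07g024600	Solyc07g049270	95.0	300	15	0	1	300	1	300	1.0e-120	518.0
Solyc07g049270	Sopen07g024600	95.0	300	15	0	1	300	1	300	1.0e-120	518.0
Sopen07g024610	Solyc07g049280	95.0	300	15	0	1	300	1	300	1.0e-120	519.0
Solyc07g049280	Sopen07g024610	95.0	300	15	0	1	300	1	300	1.0e-120	519.0
Sopen07g024620	Solyc07g049290	95.0	300	15	0	1	300	1	300	1.0e-120	520.0
Solyc07g049290	Sopen07g024620	95.0	300	15	0	1	300	1	300	1.0e-120	520.0
Sopen07g024630	Solyc07g049300	95.0	300	15	0	1	300	1	300	1.0e-120	521.0
Solyc07g049300	Sopen07g024630	95.0	300	15	0	1	300	1	300	1.0e-120	521.0
Sopen07g024450	Solyc07g048030	80.0	300	60	0	1	300	1	300	1.0e-40	300.0
Sopen07g025130	Solyc07g049150	80.0	300	60	0	1	300	1	300	1.0e-40	301.0
Sopen07g025140	Solyc07g049160	80.0	300	60	0	1	300	1	300	1.0e-40	302.0
Sopen07g025160	Solyc07g049180	80.0	300	60	0	1	300	1	300	1.0e-40	303.0
Sopen07g024640	Solyc07g049310	80.0	300	60	0	1	300	1	300	1.0e-40	304.0
Sopen07g024520	Solyc07g048100	90.0	300	30	0	1	300	1	300	1.0e-90	450.0
Solyc07g048100	Sopen07g024520	90.0	300	30	0	1	300	1	300	1.0e-90	450.0
Sopen07g024530	Solyc07g048100	90.0	300	30	0	1	300	1	300	1.0e-90	445.0
Solyc07g048100	Sopen07g024530	90.0	300	30	0	1	300	1	300	1.0e-90	445.0
Sopen07g025260	Solyc07g049240	90.0	300	30	0	1	300	1	300	1.0e-90	452.0
Solyc07g049240	Sopen07g025260	90.0	300	30	0	1	300	1	300	1.0e-90	452.0
Sopen07g025270	Solyc07g049240	90.0	300	30	0	1	300	1	300	1.0e-90	447.0
Solyc07g049240	Sopen07g025270	90.0	300	30	0	1	300	1	300	1.0e-90	447.0
Solyc07g049120	Sopen07g024560	90.0	300	30	0	1	300	1	300	1.0e-90	460.0
Sopen07g024560	Solyc07g049120	90.0	300	30	0	1	300	1	300	1.0e-90	460.0
Solyc07g049130	Sopen07g024560	90.0	300	30	0	1	300	1	300	1.0e-90	455.0
Sopen07g024560	Solyc07g049130	90.0	300	30	0	1	300	1	300	1.0e-90	455.0
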