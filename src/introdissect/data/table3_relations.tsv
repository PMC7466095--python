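# Homologous relationships between S. pennellii (v2) and S. lycopersicum M82
# (iTAG4.1) genes in the introgressed region of the tomato chromosome-7
# sub-line R182, transcribed from the published homology table of that study.
# Coordinates are printed as in the source: donor genes on the minus strand
# are listed end-before-start; readers normalize to start <= end, strand '-'.
# The Sopen07g024590 row is printed BBH with no named background partner
# (flag partner_unlisted); the partner gene is not invented here.
donor_id	donor_pos	background_id	background_pos	relation	flags
Sopen07g024420	69836210-69837672	Solyc07g047990	59085047-59086521	BBH	.
Sopen07g024430	69841308-69844381	Solyc07g048000	59090799-59093868	BBH	.
Sopen07g024440	69850538-69845963	Solyc07g048010	59095485-59099806	BBH	.
.	.	Solyc07g048020	59102011-59102233	background_specific	.
Sopen07g024450	69857939-69861502	Solyc07g048030	59104838-59109134	Homology	.
Sopen07g024460	69872065-69870851	Solyc07g048040	59117929-59119147	BBH	.
Sopen07g024470	69877402-69876191	Solyc07g048050	59122683-59123895	BBH	.
Sopen07g024480	69881212-69881726	Solyc07g048060	59127565-59128135	BBH	.
Sopen07g024490	69907539-69909885	Solyc07g048070	59139843-59142138	BBH	.
Sopen07g024500	69913450-69920824	Solyc07g048080	59154590-59161915	BBH	.
Sopen07g024510	69913450-69920824	Solyc07g048090	59163902-59164601	BBH	.
Sopen07g024520	69931348-69933371	Solyc07g048100	59171269-59183106	duplicated_donor	.
Sopen07g024530	69933372-69943849	Solyc07g048100	59171269-59183106	duplicated_donor	.
Sopen07g024540	69954645-69945131	Solyc07g048110	59184257-59193776	BBH	.
Sopen07g024550	69963499-69970741	Solyc07g048120	59201061-59208384	BBH	.
Sopen07g024560	69963499-69970741	Solyc07g049120	59262651-59264650	duplicated_background	.
Sopen07g024560	69985256-69983275	Solyc07g049130	59271800-59273866	duplicated_background	.
Sopen07g024570	70060300-70061901	.	.	donor_specific	.
Sopen07g024580	70063119-70066285	.	.	donor_specific	.
.	.	Solyc07g049135	59285823-59287144	background_specific	.
Sopen07g025130	70795423-70792524	Solyc07g049150	59334801-59337935	Homology	.
Sopen07g025140	70801910-70802955	Solyc07g049160	59338338-59343917	Homology	.
Sopen07g025150	70806557-70803357	.	.	donor_specific	.
Sopen07g025160	70829776-70818613	Solyc07g049180	59357724-59365031	Homology	.
Sopen07g025170	70830302-70828932	Solyc07g049190	59367367-59368442	BBH	.
Sopen07g025180	70837317-70844338	.	.	donor_specific	.
Sopen07g025190	70849697-70850207	.	.	donor_specific	.
Sopen07g025200	70863988-70860217	.	.	donor_specific	.
Sopen07g025210	70872807-70875563	Solyc07g049200	59414636-59417346	BBH	.
Sopen07g025220	70887686-70877146	Solyc07g049210	59417423-59423173	BBH	.
.	.	Solyc07g049215	59423182-59423459	background_specific	.
Sopen07g025230	70893995-70900317	Solyc07g049220	59429382-59435129	BBH	.
Sopen07g025240	70901562-70901131	Solyc07g049230	59435955-59436387	BBH	.
Sopen07g025250	70910568-70905495	.	.	donor_specific	.
Sopen07g025260	70913034-70928413	Solyc07g049240	59441214-59442531	duplicated_donor	.
Sopen07g025270	70941837-70943160	Solyc07g049240	59441214-59442531	duplicated_donor	.
Sopen07g025280	70947923-70947081	Solyc07g049250	59443278-59444166	BBH	.
Sopen07g024590	70071789-70067951	.	.	BBH	partner_unlisted
Sopen07g024600	70075960-70073928	Solyc07g049270	59453256-59455454	BBH	.
Sopen07g024610	70084047-70076418	Solyc07g049280	59455644-59463344	BBH	.
Sopen07g024620	70087391-70084477	Solyc07g049290	59463688-59466693	BBH	.
Sopen07g024630	70094146-70090740	Solyc07g049300	59469239-59473026	BBH	.
Sopen07g024640	70111740-70120667	Solyc07g049310	59479929-59488648	Homology	.
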