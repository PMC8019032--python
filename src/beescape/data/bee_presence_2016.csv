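taxon,visits_T1,visits_T2,visits_T3,visits_T4,visits_total,T1,T2,T3,T4,sites_total
Andrena,154,117,229,16,516,9,13,10,4,23
Apis,794,742,433,486,2455,11,11,16,14,22
Augochlora,0,9,0,0,9,0,3,0,0,3
Augochlorella,43,25,8,8,84,8,6,3,3,14
Bombus,263,406,606,940,2215,11,17,17,21,26
Ceratina,40,26,34,12,112,3,5,2,3,10
Colletes,0,7,2,2,11,0,2,1,1,3
Halictus,111,249,159,18,537,10,20,6,4,22
Heriades,0,0,3,0,3,0,0,1,0,1
Hoplitis,0,12,9,0,21,0,2,2,0,4
Hylaeus,2,28,0,0,30,1,2,0,0,3
Lasioglossum,200,225,166,31,622,18,17,16,12,26
Megachile,0,47,52,19,118,0,8,5,3,12
Melissodes,0,2,0,25,27,0,1,0,3,4
Osmia,26,10,4,0,40,4,1,1,0,5
Peponapis,0,2,482,1035,1519,0,1,12,16,20
Perdita,0,0,0,12,12,0,0,0,1,1
Sphecodes,0,1,0,3,4,0,1,0,1,1
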