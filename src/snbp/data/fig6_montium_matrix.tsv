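# Presence (1) / pseudogene (P) of six otherwise-conserved genes across an
# eleven-species representation of the montium clade (tree in
# montium_tree.nwk). Three genes were pseudogenized once on the stem branch
# (all species lack them); Mst77F was lost once in the large subclade that
# excludes D_truncata and D_mayri; Prtl99C was lost twice and CG34269 five
# times, each loss in a separate lineage. Dollo parsimony over this matrix
# yields 11 independent pseudogenization events, matching the published
# per-gene loss counts (CG34269: 5, Prtl99C: 2, Mst77F: 1, Mst33A: 1,
# CG14835: 1, tHMG: 1). The species-level pattern is a consistent
# reconstruction, not a verbatim transcription.
gene	D_kikkawai	D_bocqueti	D_jambulina	D_chauvacae	D_triauraria	D_fuyamai	D_serrata	D_bunnanda	D_birchii	D_truncata	D_mayri
CG14835	P	P	P	P	P	P	P	P	P	P	P
Mst33A	P	P	P	P	P	P	P	P	P	P	P
tHMG	P	P	P	P	P	P	P	P	P	P	P
Mst77F	P	P	P	P	P	P	P	P	P	1	1
Prtl99C	P	P	1	1	1	1	P	P	P	1	1
CG34269	P	1	P	1	1	P	1	1	P	P	1
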