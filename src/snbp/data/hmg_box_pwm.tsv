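#threshold 50.0
# log-odds PWM for a 25-residue HMG-box-like motif; consensus PKRPMSAYMLWLNSARESIKRENPG
pos	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
0	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	3.5850	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479
1	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	3.5850	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479
2	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	3.5850	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479
3	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	3.5850	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479
4	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	3.5850	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479
5	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	3.5850	-1.2479	-1.2479	-1.2479	-1.2479
6	3.5850	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479
7	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	3.5850
8	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	3.5850	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479
9	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	3.5850	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479
10	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	3.5850	-1.2479
11	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	3.5850	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479
12	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	3.5850	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479
13	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	3.5850	-1.2479	-1.2479	-1.2479	-1.2479
14	3.5850	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479
15	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	3.5850	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479
16	-1.2479	-1.2479	-1.2479	3.5850	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479
17	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	3.5850	-1.2479	-1.2479	-1.2479	-1.2479
18	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	3.5850	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479
19	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	3.5850	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479
20	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	3.5850	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479
21	-1.2479	-1.2479	-1.2479	3.5850	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479
22	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	3.5850	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479
23	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	3.5850	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479
24	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	3.5850	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479	-1.2479
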