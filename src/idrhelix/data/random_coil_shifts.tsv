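# Default random-coil chemical-shift reference table (ppm), compiled from
# standard intrinsically-disordered reference-peptide values. Glycine has no
# CB; proline has no amide H. Conditions: ~pH 6.5, 25 C; correction schemes
# (neighbor, temperature, pH) are swappable via RandomCoilTable.from_tsv.
residue	atom	shift_ppm
A	CA	52.8
A	CB	19.0
A	C	178.4
A	H	8.35
A	N	123.8
R	CA	56.5
R	CB	30.9
R	C	177.1
R	H	8.40
R	N	121.2
N	CA	53.3
N	CB	39.1
N	C	175.7
N	H	8.51
N	N	119.0
D	CA	54.5
D	CB	41.1
D	C	177.0
D	H	8.44
D	N	120.4
C	CA	58.6
C	CB	28.3
C	C	175.3
C	H	8.54
C	N	118.8
Q	CA	56.2
Q	CB	29.5
Q	C	176.5
Q	H	8.44
Q	N	120.5
E	CA	56.8
E	CB	30.3
E	C	177.1
E	H	8.42
E	N	121.3
G	CA	45.4
G	C	174.6
G	H	8.41
G	N	109.5
H	CA	55.5
H	CB	29.4
H	C	175.1
H	H	8.56
H	N	119.1
I	CA	61.6
I	CB	38.9
I	C	176.8
I	H	8.17
I	N	121.5
L	CA	55.5
L	CB	42.5
L	C	178.0
L	H	8.28
L	N	122.4
K	CA	56.7
K	CB	33.2
K	C	177.1
K	H	8.36
K	N	121.6
M	CA	55.8
M	CB	32.9
M	C	176.8
M	H	8.42
M	N	120.7
F	CA	58.1
F	CB	39.8
F	C	176.2
F	H	8.34
F	N	120.7
P	CA	63.3
P	CB	32.0
P	C	177.3
P	N	137.0
S	CA	58.7
S	CB	63.9
S	C	175.2
S	H	8.43
S	N	116.5
T	CA	62.0
T	CB	69.8
T	C	175.1
T	H	8.25
T	N	114.5
W	CA	57.6
W	CB	29.8
W	C	176.6
W	H	8.22
W	N	121.8
Y	CA	58.0
Y	CB	38.8
Y	C	176.1
Y	H	8.26
Y	N	120.9
V	CA	62.6
V	CB	32.8
V	C	176.6
V	H	8.16
V	N	121.1
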