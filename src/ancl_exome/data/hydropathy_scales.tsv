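# Per-residue physicochemical scales.
# kd:  Kyte & Doolittle (1982) J Mol Biol 157:105 hydropathy index.
# ww_interface: Wimley & White (1996) Nat Struct Biol 3:842 whole-residue free
#   energy of transfer, water -> POPC bilayer interface (kcal/mol; negative =
#   favorable partitioning).  Charged Asp/Glu/Lys/Arg, neutral His.
# ww_octanol: Wimley, Creamer & White (1996) Biochemistry 35:5109 whole-residue
#   water -> n-octanol transfer free energy (kcal/mol), same charge states.
residue	kd	ww_interface	ww_octanol
A	1.8	0.17	0.50
R	-4.5	0.81	1.81
N	-3.5	0.42	0.85
D	-3.5	1.23	3.64
C	2.5	-0.24	-0.02
Q	-3.5	0.58	0.77
E	-3.5	2.02	3.63
G	-0.4	0.01	1.15
H	-3.2	0.17	0.11
I	4.5	-0.31	-1.12
L	3.8	-0.56	-1.25
K	-3.9	0.99	2.80
M	1.9	-0.23	-0.67
F	2.8	-1.13	-1.71
P	-1.6	0.45	0.14
S	-0.8	0.13	0.46
T	-0.7	0.14	0.25
W	-0.9	-1.85	-2.09
Y	-1.3	-0.94	-0.71
V	4.2	0.07	-0.46
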