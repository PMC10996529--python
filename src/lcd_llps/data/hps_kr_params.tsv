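residue	mass_amu	charge_e	lambda	sigma_nm
A	71.08	0	0.72973	0.504
R	156.19	1	0.00000	0.656
N	114.10	0	0.43243	0.568
D	115.09	-1	0.37838	0.558
C	103.14	0	0.59459	0.548
Q	128.13	0	0.51351	0.602
E	129.12	-1	0.45946	0.592
G	57.05	0	0.64865	0.450
H	137.14	0	0.51351	0.608
I	113.16	0	0.97297	0.618
L	113.16	0	0.97297	0.618
K	128.17	1	0.51351	0.636
M	131.19	0	0.83784	0.618
F	147.18	0	1.00000	0.636
P	97.12	0	1.00000	0.556
S	87.08	0	0.59459	0.518
T	101.10	0	0.67568	0.562
W	186.21	0	0.94595	0.678
Y	163.18	0	0.86486	0.646
V	99.07	0	0.89189	0.586
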