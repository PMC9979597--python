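# COGITO bond-stretching parameters: bead i, bead j, r_eq (nm), k_b (kJ mol^-1 nm^-2)
bead_i	bead_j	r_eq	k_b
1CH2OCO	2CHOCO	0.470	4000
1CH2OCO	C2H4E	0.300	5000
1CH2OCO	C3H6E	0.365	5000
2CHOCO	3CH2OCO	0.350	4000
2CHOCO	C2H4E	0.300	5000
2CHOCO	C3H6E	0.360	5000
3CH2OCO	C2H4E	0.290	5000
3CH2OCO	C3H6E	0.350	5000
CHCH	C3H6	0.340	3000
C2H4E	C2H4	0.280	3000
C2H4E	C3H6	0.335	3000
C2H4	C3H6	0.345	3000
C2H4	C3H7T	0.345	3000
C3H6E	C3H6	0.400	3000
C3H6	C3H6	0.400	3000
C3H6	C3H7T	0.400	3000
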