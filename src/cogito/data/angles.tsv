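# COGITO angle-vibration parameters: beads i, j (vertex), k, theta_eq (deg), k_theta (kJ mol^-1)
bead_i	bead_j	bead_k	theta_eq	k_theta
1CH2OCO	2CHOCO	3CH2OCO	65	120
1CH2OCO	2CHOCO	C2H4E	147	100
1CH2OCO	2CHOCO	C3H6E	140	100
1CH2OCO	C2H4E	C2H4	166	50
1CH2OCO	C2H4E	C3H6	171	50
1CH2OCO	C3H6E	C3H6	157	50
2CHOCO	1CH2OCO	C2H4E	144	100
2CHOCO	1CH2OCO	C3H6E	145	100
2CHOCO	3CH2OCO	C2H4E	126	35
2CHOCO	3CH2OCO	C3H6E	131	35
2CHOCO	C2H4E	C2H4	168	50
2CHOCO	C2H4E	C3H6	172	50
2CHOCO	C3H6E	C3H6	158	50
3CH2OCO	2CHOCO	C2H4E	117	35
3CH2OCO	2CHOCO	C3H6E	118	35
3CH2OCO	C2H4E	C2H4	97	50
3CH2OCO	C2H4E	C3H6	105	50
3CH2OCO	C3H6E	C3H6	118	50
CHCH	C3H6	C2H4	159	35
C2H4E	C2H4	C3H6	174	35
C2H4E	C3H6	C3H6	164	35
C2H4	C3H6	C3H6	166	35
C3H6E	C3H6	C3H6	165	35
C3H6	CHCH	C3H6	101	35
C3H6	C2H4	C3H7T	178	35
C3H6	C3H6	C3H6	163	35
C3H6	C3H6	C3H7T	165	35
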