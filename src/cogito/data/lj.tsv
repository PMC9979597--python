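# COGITO Lennard-Jones non-bonded parameters: bead, sigma (nm), epsilon (kJ mol^-1)
bead	sigma	epsilon
1CH2OCO	0.431	4.661
2CHOCO	0.442	4.781
3CH2OCO	0.434	4.374
CHCH	0.415	2.584
C2H4E	0.408	2.598
C2H4	0.412	2.384
C3H6E	0.386	2.800
C3H6	0.465	3.188
C3H7T	0.426	2.689
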