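# COGITO bead types: name, heavy-atom composition, partial charge (e), description
# Bead masses are derived from the composition at load time.
name	composition	charge	description
1CH2OCO	C:2,H:2,O:2	-0.05	sn-1 glycerol carbon plus ester group
2CHOCO	C:2,H:1,O:2	-0.05	sn-2 glycerol carbon plus ester group
3CH2OCO	C:2,H:2,O:2	-0.05	sn-3 glycerol carbon plus ester group
CHCH	C:2,H:2	0	CH=CH alkene bead
C2H4E	C:2,H:4	0.05	CH2CH2 bead adjacent to a glycerol-ester bead
C2H4	C:2,H:4	0	CH2CH2 bead not adjacent to a glycerol-ester bead
C3H6E	C:3,H:6	0.05	CH2CH2CH2 bead adjacent to a glycerol-ester bead
C3H6	C:3,H:6	0	CH2CH2CH2 bead not adjacent to a glycerol-ester bead
C3H7T	C:3,H:7	0	terminal CH2CH2CH3 bead
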