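18	SULFONAMIDE S	[$([SD4]([OD1,ND2])[OD1,ND2]),$([SD3](=C)([OD1,ND2])[OD1,ND2])]	S
17	SULFOXIDE S	[$([SD3]([OD1,ND2])([#6,#7D3,#8D2])[#6,#7D3,#8D2])]	S
73	SULFUR IN SULFINATE	[$([SD3]([OD1,SD1])[OD1])]	S
44	S IN THIOPHENE	[sD2r500]	S
15	THIOL, SULFIDE	[$([SD2](-*)-*)]	S
74	SULFINYL SULFUR, C=S=O	[$([SD2]([CD3])[OD1])]	S
72	THIOCARBOXYLATE S	[$([SD1][CD3][SD1])]	S
16	S DOUBLY BONDED TO C	[$([SD1]=[#6D3])]	S
72	TERMINAL SULFUR ON SPO, SCO, SSO	[$([SD1][#15,#6,#16][OD1])]	S
72	TERMINAL SULFUR ON C	[$([SD1][#6])]	S
72	TERMINAL SULFUR ON P or S	[$([SD1][#15,#16])]	S
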