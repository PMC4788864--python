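# Default reference anchors for subfamily/subgroup assignment: previously
# characterized plant MATE transporters and the subgroup each marks.
# Editable; leaf names must match the labels in the input tree.
leaf	subgroup
AtFFT	C1-1
SlMATE	C1-1
VvAM1	C1-1
VvAM3	C1-1
AtTT12	C1-3
MtMATE1	C1-3
NtMATE1	C1-3
NtMATE2	C1-3
VvMATE1	C1-3
AtALF5	C2-1
AtDTX1	C2-2
NtJAT1	C2-2
AtADS1	C3-2
AtDTX50	C3-2
AtZF14	C3-2
AtEDS5	C4-2
SbMATE	C4-3
HvAACT1	C4-3
BoMATE	C4-3
EcMATE1	C4-3
OsFRDL4	C4-3
ZmMATE1	C4-3
GmFRD3b	C4-3
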