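token	sublobar
MTS	MT
MT	MT
LT	LT
MLT	MLT
F	F
P	P
O	O
I	I
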