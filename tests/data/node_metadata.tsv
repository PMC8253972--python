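node_id	network	lobe	hemisphere
n0	MF	PFC	L
n1	MF	PFC	R
n2	FP	Par	L
n3	FP	Par	R
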