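subject_id	n1–n0	n2–n0	n2–n1	n3–n0	n3–n1	n3–n2
p1	0.12	-0.18	0.30	0.08	0.38	-0.10
p2	-0.28	0.22	0.12	0.40	-0.08	0.18
p3	0.48	0.08	-0.22	0.12	0.28	0.12
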