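subject_id	n1–n0	n2–n0	n2–n1	n3–n0	n3–n1	n3–n2
c1	0.10	-0.20	0.35	0.05	0.40	-0.15
c2	-0.30	0.25	0.10	0.45	-0.05	0.20
c3	0.50	0.05	-0.25	0.15	0.30	0.10
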