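child_id	parent_id
c1	p1
c2	p9
c3	p3
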