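subject_id	sex	timepoint	mean_fd	testosterone	cbcl
c1	F	age11	0.08	3.6	9.5
c2	M	age11	0.12		12.0
c3	F	age11	0.10	5.1	
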