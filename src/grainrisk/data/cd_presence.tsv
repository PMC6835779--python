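epitope_id	REF	1	2	3	4	5
7	X	X	X	X	X
42	X	X	X		X
45	X		X
53	X	X	X		X
64	X		X
93	X	X	X	X	X
138	X
151	X	X	X	X
152	X	X	X	X
164	X	X	X		X
166	X	X	X		X
185	X		X
187	X	X	X	X	X
224	X
235	X
976	X	X	X	X
867	X	X	X	X	X
891	X	X	X	X	X
911	X	X	X	X	X
926	X	X	X	X	X
930	X	X	X		X
935	X	X	X	X	X
458	X	X	X
464	X		X
468	X		X
502	X	X	X		X
503	X	X	X		X
504	X	X	X		X
534	X	X	X	X
553	X	X	X	X	X
644	X
650	X
701	X	X	X	X		X
751	X	X	X	X		X
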