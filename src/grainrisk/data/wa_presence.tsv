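epitope_id	REF	1	2	3	4	5
148993	X	X	X	X	X
148736	X	X	X	X	X
148860	X			X	X	X
192607	X
52105	X	X	X	X	X
148610	X		X
148713	X	X	X	X	X
148748	X
148762	X		X
148828	X		X		X
148834	X		X	X	X
148841	X	X	X	X	X
148843	X
148856	X		X
148857	X		X		X
148898	X
173928	X		X
173960			X
173967	X
173992	X		X
190740	X
190898	X		X		X
190900	X	X	X	X		X
190924	X				X
190931	X	X	X	X		X
190932		X	X
52600	X	X	X	X	X
113765	X	X	X		X	X
113766			X
113781	X
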