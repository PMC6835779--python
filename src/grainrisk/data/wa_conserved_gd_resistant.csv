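epitope_id
17333
38950
49082
49087
49097
51922
52028
52097
52124
113686
113755
113778
113779
148605
148711
148719
148737
148807
148844
148845
173980
174249
174250
192579
431006
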