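epitope_id,disease,sequence,restriction_or_allergen,source_protein_label,core_names
7,CD,PQPQPFPSQQPY,HLA-DR,α-gliadin,
42,CD,QPFPQPQLPY,DQ2,α-gliadin,DQ2.5-glia-α1a
45,CD,PFPQPQLPYPQ,DQ2,α-gliadin,DQ2.5-glia-α1a;DQ2.5-glia-α2
53,CD,PFPQPQLPY,DQ2.5,α-9 gliadin,DQ2.5-glia-α1a
64,CD,PQPQLPYPQPQL,DQ2,α-gliadin,DQ2.5-glia-α2
93,CD,FRPQQPYPQ,DQ2.5,α-20 gliadin,DQ2.5-glia-α3
138,CD,PQQPYPQPQPQ,DQ2,α-gliadin,
151,CD,LGQQQPFPPQQPYPQPQ,"DQ2 (α1 * 0501, α1 * 0201)",α-gliadin,
152,CD,LGQQQPFPPQQPY,HLA-DR,α-gliadin,
164,CD,QPFPQPQLPYSQ,DQ2,α-gliadin,DQ2.5-glia-α1a
166,CD,PFPQPQLPYSQ,DQ2,α-gliadin,DQ2.5-glia-α1a
185,CD,QPQPFLPQLPYPQP,DQ2,α-gliadin,
187,CD,PQPFLPQLPYPQ,DQ2,α-gliadin,
224,CD,PLQPQQPFPQQPQQPFPQPQ,DQ2,ω-gliadin,DQ2.5-glia-γ4c;DQ2.5-glia-γ5;DQ8-glia-γ1a
235,CD,PQQPQQPFPLQPQQPFPQQP,DQ8,ω-gliadin,
976,CD,QPFPLQPQQPVPQQPQ,DQ2,ω-gliadin,
867,CD,PFPQPQQPF,DQ2.5,hor-1,DQ2.5-glia-ω1;DQ2.5-hor-1;DQ2.5-sec-1
891,CD,PQPQQPFPQ,DQ2.5,hor-2,DQ2.5-hor-2;DQ2.5-sec-2
911,CD,PQQPFPQPQQPFPQ,DQ2,ω-gliadin,DQ2.5-glia-ω1;DQ2.5-hor-1;DQ2.5-hor-2;DQ2.5-sec-1;DQ2.5-sec-2
926,CD,PQTQQPQQPFPQ,DQ2,γ-gliadin,DQ2.5-glia-γ4c;DQ8-glia-γ1a
930,CD,QSIPQPQQPFPQ,DQ2,γ-gliadin,DQ2.5-hor-2;DQ2.5-sec-2
935,CD,QPFPQPQQPFPQ,DQ2,γ-gliadin,DQ2.5-glia-ω1;DQ2.5-hor-1;DQ2.5-hor-2;DQ2.5-sec-1;DQ2.5-sec-2
458,CD,QQPQQPYPQ,DQ2.5/DQ8,γ-1 and γ-5 gliadin,DQ2.5-glia-γ3;DQ8-glia-γ1b
464,CD,QQPYPQQPQ,DQ2,γ-gliadin,
468,CD,PYPQQPQQP,DQ2,γ-gliadin,
502,CD,PFPQPQQTFPQQPQLPFPQQ,"DQ2, DQ8",γ1-gliadin,
503,CD,PFPQPQQTFPQ,DQ2,γ1-gliadin,
504,CD,PQQTFPQQPQLP,DQ2,γ1-gliadin,
534,CD,TQQPQQPFPQP,DQ2,γ-gliadin,DQ2.5-glia-γ4c;DQ8-glia-γ1a
553,CD,PFPQTQQPQQPFPQ,DQ8 (DQ2/8),γ-gliadin,DQ2.5-glia-γ4c;DQ8-glia-γ1a
644,CD,PFPQPQQPQQPFPQ,DQ8 (DQ2/8),γ-gliadin,DQ2.5-glia-γ4c;DQ8-glia-γ1a
650,CD,QPFPQLQQPQQP,DQ2,γ-gliadin,
701,CD,QQPPFSQQQQPVLPQ,DQ2,γ-gliadin or LMW glutenin,DQ2.2-glut-L1
751,CD,QQPPFSQQQQPQFSQ,DQ2,LMW glutenin,
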