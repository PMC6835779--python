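epitope_id,disease,sequence,restriction_or_allergen,source_protein_label,core_names
148993,WA,YLQLQPFPQP,Tri a 21,α-gliadin,
148736,WA,PQQPFPQLQQ,Tri a 20,γ-gliadin,
148860,WA,QQQLPQPQQP,Tri a 20,γ-gliadin,
192607,WA,QQPVPQPHQPFSQQ,Tri a 20,γ-gliadin,
52105,WA,QQPQQPFPLQ,Tri a 19,ω-gliadin,
148610,WA,FPQQQFPQQQ,Tri a 19,ω-gliadin,
148713,WA,PFPQPQQPFP,Tri a 19,ω-gliadin,
148748,WA,PQQSPEQQQF,Tri a 19,ω-gliadin,
148762,WA,QFPQQQFPQQ,Tri a 19,ω-gliadin,
148828,WA,QQFPQQQFPQ,Tri a 19,ω-gliadin,
148834,WA,QQLQQPFPLQ,Tri a 19,ω-gliadin,
148841,WA,QQPIPVQPQQ,Tri a 19,ω-gliadin,
148843,WA,QQPQQPFPQL,Tri a 19,ω-gliadin,
148856,WA,QQQFPQQPPQ,Tri a 19,ω-gliadin,
148857,WA,QQQFPQQQFP,Tri a 19,ω-gliadin,
148898,WA,QSPEQQQFPQ,Tri a 19,ω-gliadin,
173928,WA,FPQQQFPQQQFPQ,Tri a 19,ω-gliadin,
173960,WA,PQQQFPQQQQFPQ,Tri a 19,ω-gliadin,
173967,WA,PQQSPEQQQFPQQ,Tri a 19,ω-gliadin,
173992,WA,QQQFPQQQFPQQP,Tri a 19,ω-gliadin,
190740,WA,EQQQFPQQQF,Tri a 19,ω-gliadin,
190898,WA,PQQPQQFPQQ,Tri a 19,ω-gliadin,
190900,WA,PQQQQFPQQQ,Tri a 19,ω-gliadin,
190924,WA,QPQQFPQQQF,Tri a 19,ω-gliadin,
190931,WA,QQFPQQQQFP,Tri a 19,ω-gliadin,
190932,WA,QQFPQQQQLP,Tri a 19,ω-gliadin,
52600,WA,QTQQPQQPFP,Tri a 19/Tri a 20,ω-gliadin or γ-gliadin,
113765,WA,QPGQGQQGQQPGQG,Tri a 26,HMW-glutenin,
113766,WA,QPGQGQQPGQGQPG,Tri a 26,HMW-glutenin,
113781,WA,QQPGQGQQPGQGQQ,Tri a 26,HMW-glutenin,
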