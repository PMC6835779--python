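epitope_id,core_name
,DQ2.5-glia-α2
,DQ2.5-glia-γ5
,DQ2.5-glia-γ4c
,DQ8-glia-γ1a
,DQ2.2-glut-L1
227,
236,
542,
648,
717,
719,
923,
1044,
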