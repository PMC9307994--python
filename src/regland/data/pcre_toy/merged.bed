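chrT	9500	10500	iv1
chrT	13500	14200	iv2
chrT	30200	30800	iv3
chrT	40000	40500	iv4
chrT	48300	48900	iv5
chrT	70000	70400	iv6
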