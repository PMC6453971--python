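a	b	identity_nt
LC386204	LC386198	56.58
LC386195	LC386196	82.29
LC386205	LC386198	99.80
LC386197	LC386198	92.86
LC386199	LC386201	79.62
LC386200	LC386202	80.14
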