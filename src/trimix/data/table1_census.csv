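region,white_pct,brown_pct,black_pct
Para,20.77,72.95,5.40
Ceara,33.05,63.39,3.03
Bahia,20.60,62.84,15.99
Rio de Janeiro,52.51,32.72,14.37
Santa Catarina,86.96,9.98,2.63
Rio Grande do Sul,80.84,13.77,4.87
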