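line,stock_class,chromosome,arm,fl
CS Dt7AS,Dt,7A,S,
CS Dt7AL,Dt,7A,L,
CS Dt7BS,Dt,7B,S,
CS Dt7BL,Dt,7B,L,
CS Dt7DS,Dt,7D,S,
CS Dt7DL,Dt,7D,L,
CS Del7AS-1,Del,7A,S,0.89
CS Del7AS-2,Del,7A,S,0.73
CS Del7AS-3,Del,7A,S,0.29
CS Del7AS-4,Del,7A,S,0.26
CS Del7AS-5,Del,7A,S,0.59
CS Del7AS-6,Del,7A,S,0.21
CS Del7AS-7,Del,7A,S,0.87
CS Del7AS-11,Del,7A,S,0.66
CS Del7AS-8,Del,7A,S,0.45
CS Del7AS-12,Del,7A,S,0.83
CS Del7AL-1,Del,7A,L,0.39
CS Del7AL-2,Del,7A,L,0.87
CS Del7AL-4,Del,7A,L,0.18
CS Del7AL-6,Del,7A,L,0.80
CS Del7AL-7,Del,7A,L,0.33
CS Del7AL-8,Del,7A,L,0.83
CS Del7AL-9,Del,7A,L,0.89
CS Del7AL-10,Del,7A,L,0.49
CS Del7AL-11,Del,7A,L,0.40
CS Del7AL-14,Del,7A,L,0.31
CS Del7AL-15,Del,7A,L,0.99
CS Del7AL-16,Del,7A,L,0.86
CS Del7AL-17,Del,7A,L,0.71
CS Del7AL-18,Del,7A,L,0.90
CS Del7AL-20,Del,7A,L,0.89
CS Del7AL-21,Del,7A,L,0.74
CS Del7BL-1,Del,7B,L,0.40
CS Del7BL-2,Del,7B,L,0.33
CS Del7BL-3,Del,7B,L,0.86
CS Del7BL-4,Del,7B,L,0.56
CS Del7BL-5,Del,7B,L,0.69
CS Del7BL-6,Del,7B,L,0.84
CS Del7BL-7,Del,7B,L,0.48
CS Del7BL-12,Del,7B,L,0.25
CS Del7BL-13,Del,7B,L,0.79
CS Del7DS-1,Del,7D,S,0.37
CS Del7DS-4,Del,7D,S,0.61
CS Del7DS-5,Del,7D,S,0.36
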