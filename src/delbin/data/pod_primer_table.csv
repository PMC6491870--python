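assay,gene,kind,forward,reverse,region_start,region_end,expected_size,annealing_c,diagnostic_allele
P1,TaPod-D1,cloning,AGCACACAAGGAGAGAGGAG,AAGAGGCACGCGGTAGTCG,-20,468,488,64,
P2,TaPod-D1,cloning,CGACTACCGCGTGCCTCTT,TAGTCCACTTGTCTAGATGCTT,450,1104,655,62,
P3,TaPod-A2,cloning,GCTACCCTTGAATCCTGCCTA,CTCGAAGGAGGAGCAGTGC,-92,660,752,64,
P4,TaPod-A2,cloning,GGACTACCGCGTGCCTCTC,GCTAGCCAAGGCTTTCTTCG,462,1090,629,64,
P5,TaPod-A3,cloning,CCTCGTCAGCGGGGTTCG,CCGTGCATTCGCATTCAAG,,,574,62,
P6,TaPod-B1,cloning,GCCTCGTCAGCGGGTTCC,CGTGCCAACACAACACACTG,,,580,62,
POD-7D6,TaPod-D1,sts,TGGGCATGGGGCTTCTGCA,GCGAGGAATGGGGGGTTGATG,,,640,58,TaPod-D1a
POD-7D1,TaPod-D1,sts,GCTTCGTCCAGGACGCCGTT,CGAGGAATGGGGGGTTGATG,,,540,61,TaPod-D1b
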