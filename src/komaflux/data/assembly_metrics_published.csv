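strain,newly_assembled,total_size_mbp,n_contigs,n50_mbp,n50_number,longest_mbp,sum_top4_mbp
K. mondaviorum CBS 15017,1,9.5,13,2.38,2,3.15,8.5
K. ulmi CBS 12361,1,9.6,11,2.74,2,3.30,9.5
K. populi CBS 12362,1,9.3,11,2.61,2,2.80,8.4
K. kurtzmanii CBS 12817,1,9.6,19,1.67,3,2.42,7.5
K. phaffii UWOPS 03-328y3,1,9.5,8,2.27,2,2.90,8.6
K. pastoris DSMZ 70877,1,9.6,8,2.72,2,3.32,9.5
K. pastoris CBS 9178,1,10.1,34,2.69,2,3.32,9.4
K. pseudopastoris CBS 9187,1,10.6,73,1.67,3,2.80,7.9
Ref. K. pastoris CBS 704,0,9.6,11,2.69,2,3.33,9.4
Ref. K. phaffii CBS 7435,0,9.4,7,2.40,2,2.89,9.4
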