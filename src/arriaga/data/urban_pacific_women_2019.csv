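age_start,n,rate,ax
0,1,0.003609,0.063104
1,4,0.000175,1.516522
5,5,0.000118,2.500000
10,5,0.000109,2.673004
15,5,0.000208,2.717355
20,5,0.000327,2.599822
25,5,0.000366,2.632594
30,5,0.000562,2.652385
35,5,0.000781,2.646976
40,5,0.001120,2.649646
45,5,0.001600,2.669022
50,5,0.002449,2.688760
55,5,0.003895,2.677877
60,5,0.005957,2.648850
65,5,0.008548,2.662720
70,5,0.013564,2.673357
75,5,0.022154,2.685871
80,5,0.040466,2.500000
85,+,0.110591,
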