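age_start,n,rate,ax
0,1,0.007655,0.074435
1,4,0.000433,1.510379
5,5,0.000185,2.500000
10,5,0.000224,2.698390
15,5,0.000399,2.625958
20,5,0.000467,2.560885
25,5,0.000538,2.609242
30,5,0.000752,2.645253
35,5,0.001069,2.651170
40,5,0.001541,2.706326
45,5,0.002628,2.706583
50,5,0.004234,2.670296
55,5,0.006295,2.681929
60,5,0.010252,2.655346
65,5,0.015119,2.644060
70,5,0.023492,2.640862
75,5,0.037778,2.614471
80,5,0.061530,2.500000
85,+,0.151531,
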