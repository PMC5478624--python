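grade,Sa_mm,Sq_mm,Ssk,Sku
1,1.28,1.46,1.26,1.66
2,4.00,4.72,1.38,2.08
3,6.94,9.96,2.16,5.66
4,9.80,12.85,1.65,3.04
5,10.93,14.90,1.70,3.22
6,17.89,27.13,1.98,4.38
7,31.83,45.63,1.74,3.31
8,36.98,52.09,1.58,2.67
9,45.29,63.51,1.64,2.87
10,52.23,73.73,1.63,2.82
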