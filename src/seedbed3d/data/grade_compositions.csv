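grade,max_grain_size_mm,frac_lt5,frac_5_15,frac_15_50,frac_50_80,frac_80_120,frac_gt120
1,4,100.0,0.0,0.0,0.0,0.0,0.0
2,12,58.9,41.1,0.0,0.0,0.0,0.0
3,22,45.6,36.7,17.7,0.0,0.0,0.0
4,34,38.8,34.6,26.6,0.0,0.0,0.0
5,48,35.3,33.0,31.7,0.0,0.0,0.0
6,64,31.2,28.6,26.3,13.9,0.0,0.0
7,82,30.9,24.2,20.6,16.7,7.6,0.0
8,102,28.3,21.1,17.8,15.6,17.2,0.0
9,122,25.5,21.7,16.7,13.2,12.3,10.6
10,142,22.3,20.3,15.2,13.0,14.5,14.7
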