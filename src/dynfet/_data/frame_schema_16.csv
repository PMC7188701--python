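frame_index,start_s,end_s
0,0,60
1,60,120
2,120,180
3,180,240
4,240,300
5,300,480
6,480,660
7,660,840
8,840,1020
9,1020,1200
10,1200,1500
11,1500,1800
12,1800,2100
13,2100,2400
14,2400,2700
15,2700,3000
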