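case_id,segment,obstetrician_1,obstetrician_2,obstetrician_3
1,initial,80,80,80
2,initial,65,66,70
3,initial,65,66,70
4,initial,63,67,65
5,initial,82,83,85
6,initial,75,76,75
7,initial,80,81,85
8,initial,84,85,80
9,initial,100,102,105
10,initial,82,82,80
11,initial,67,65,70
12,initial,75,74,87
13,initial,70,70,70
1,last,78,75,75
2,last,90,90,100
3,last,70,67,70
4,last,70,65,65
5,last,87,87,90
6,last,72,73,75
7,last,75,75,75
8,last,100,98,100
9,last,110,108,110
10,last,103,103,100
11,last,80,80,100
12,last,98,100,100
13,last,70,70,65
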