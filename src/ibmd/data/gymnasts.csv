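case_id,rulebook,judge_1,judge_2,judge_3,judge_4,judge_5,judge_6,judge_7,judge_8
1,old,7.10,7.20,7.00,7.70,7.10,7.10,7.00,7.30
2,old,9.30,9.70,8.90,9.60,8.60,9.50,9.60,9.70
3,old,8.90,8.80,8.10,9.30,8.50,8.10,7.60,8.70
4,old,8.00,8.10,7.30,8.70,7.50,8.70,7.40,9.50
5,old,9.10,9.00,8.20,9.00,8.20,9.50,7.80,8.00
6,old,9.10,9.20,8.30,9.10,7.90,8.90,9.00,9.20
7,old,8.90,9.00,7.70,9.00,8.00,9.40,8.00,7.70
8,old,8.30,8.70,8.10,8.90,7.80,9.20,7.80,9.30
9,old,9.30,9.40,8.20,9.40,8.80,9.30,9.20,9.80
10,old,9.40,9.80,9.40,9.70,9.10,10.00,9.30,9.60
11,old,7.70,8.70,7.60,9.00,7.70,8.50,7.70,7.70
12,old,9.20,9.70,8.50,9.60,8.60,9.90,9.70,7.40
13,old,7.40,7.30,7.10,7.90,7.10,7.40,7.00,7.50
14,old,8.40,8.90,7.40,8.60,7.80,8.10,7.40,8.90
15,old,7.40,7.60,7.10,8.10,7.20,7.60,7.10,8.80
16,old,9.80,9.90,9.20,9.80,9.30,10.00,9.40,9.60
17,old,9.60,9.60,9.50,9.80,9.10,9.90,9.40,9.90
18,old,9.60,9.80,9.50,9.80,8.80,9.90,9.80,9.20
19,old,8.50,9.20,7.80,9.30,7.90,9.00,7.70,9.70
20,old,7.10,9.50,8.80,9.40,8.50,9.60,7.90,8.50
21,new,6.50,8.20,6.60,9.80,7.50,7.80,6.10,5.10
22,new,7.00,9.70,7.60,9.60,8.30,6.90,6.70,8.60
23,new,7.50,8.60,6.60,7.80,9.50,8.10,6.20,7.60
24,new,8.50,9.00,8.10,7.00,8.30,9.40,6.70,8.00
25,new,9.70,8.10,7.50,6.80,7.70,8.60,8.30,7.40
26,new,8.00,9.10,7.40,9.30,8.30,9.70,6.00,9.90
27,new,7.80,9.70,7.00,9.70,8.70,10.00,9.60,9.50
28,new,9.30,7.90,8.20,7.80,6.30,7.40,6.10,7.20
29,new,7.10,9.80,8.10,9.50,6.30,9.40,8.90,6.50
30,new,8.90,9.30,7.90,6.80,8.20,9.10,7.90,6.80
31,new,9.30,9.80,8.80,6.60,8.50,9.80,7.40,9.90
32,new,7.90,8.20,6.70,9.40,7.60,6.10,7.40,7.10
33,new,7.60,8.50,6.40,8.50,9.20,7.80,6.20,9.40
34,new,8.60,8.90,6.50,9.00,7.70,9.10,6.50,7.10
35,new,8.80,7.20,8.80,9.30,8.40,9.30,6.90,8.60
36,new,8.40,9.30,7.50,8.70,7.90,9.60,7.90,7.90
37,new,7.50,8.00,7.20,8.40,7.40,7.20,9.10,9.20
38,new,9.70,9.80,9.50,9.80,9.00,9.90,9.40,9.60
39,new,8.50,9.20,8.70,9.30,7.00,9.70,8.30,8.00
40,new,7.30,8.70,7.20,8.10,7.30,7.30,7.10,7.20
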