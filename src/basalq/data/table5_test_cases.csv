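test_number,hba1c_level,bmi_level,activity_level,alcohol_level,actual_dose,action_index,printed_match
1,1,7,1,1,6,1,match
2,1,2,1,1,14,1,match
3,2,5,1,1,12,1,match
4,2,7,1,1,20,1,not match
5,2,4,1,1,14,1,match
6,2,5,1,1,10,1,match
7,2,6,1,1,12,1,match
8,2,8,1,1,20,3,match
9,2,4,1,1,20,3,match
10,2,11,1,1,25,3,match
11,2,10,1,1,25,3,match
12,2,8,1,1,13,3,not match
13,2,6,1,1,10,1,match
14,2,2,1,1,11,1,match
15,2,4,1,1,12,1,match
16,2,5,1,1,13,1,match
17,2,7,1,1,22,1,not match
18,2,4,1,1,8,1,match
19,2,4,1,1,6,1,match
20,2,4,1,1,9,1,match
21,2,5,1,1,10,1,match
22,2,5,1,1,14,1,match
23,2,8,1,2,15,1,match
24,2,14,1,2,20,3,match
25,2,8,1,2,18,1,not match
26,2,5,1,2,14,1,match
27,2,5,1,2,14,1,match
28,2,5,1,2,8,1,match
29,2,8,1,2,15,1,match
30,2,5,1,2,11,1,match
31,2,5,1,2,10,1,match
32,2,4,1,2,9,1,match
33,2,6,1,3,20,3,match
34,2,5,1,3,20,3,match
35,2,5,1,3,20,3,match
36,1,6,1,3,20,2,match
37,3,12,2,1,46,4,not match
38,1,5,2,1,15,2,match
39,1,7,2,1,20,2,match
40,1,5,2,1,15,2,match
41,2,8,2,1,25,3,match
42,2,10,2,1,30,3,match
43,3,13,2,1,50,4,not match
44,2,8,2,1,21,3,match
45,2,6,2,1,20,3,match
46,2,8,2,1,28,3,match
47,2,6,2,1,20,3,match
48,2,7,2,1,20,2,match
49,3,12,2,1,50,6,match
50,3,17,2,1,70,6,match
51,3,17,2,1,80,6,match
52,2,8,2,1,25,3,match
53,2,6,2,1,30,3,match
54,3,12,2,1,50,4,not match
55,3,11,2,1,36,4,match
56,3,11,2,1,38,4,match
57,2,8,2,1,21,3,match
58,2,9,2,1,23,3,match
59,2,9,2,1,23,3,match
60,2,7,2,1,20,3,match
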