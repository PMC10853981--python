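id,age,sex,affected_hand,days_post_stroke,nihss_day0,mrs,arat_w3,fmue_w3,arat_w12,fmue_w12,second_meg
1,49,M,R,26,8,3,3,18,9,33,0
2,50,M,R,24,5,3,17,38,41,51,1
3,41,F,R,28,5,3,3,20,9,33,1
4,57,M,L,17,3,2,38,50,,,0
5,75,F,L,20,5,3,20,20,35,33,1
6,59,M,R,14,2,2,57,66,,,0
7,61,M,R,25,1,1,57,66,57,66,0
8,68,F,L,20,1,1,54,58,57,66,1
9,55,F,L,24,6,3,13,50,55,65,1
10,52,M,L,14,3,3,34,52,53,64,0
11,56,M,R,16,1,2,54,65,57,66,1
12,75,M,L,27,12,4,4,21,,,0
13,74,F,L,23,7,4,6,23,,,0
14,61,M,R,28,4,3,3,16,20,50,1
15,34,M,R,21,4,1,57,65,57,66,0
16,64,M,L,15,8,4,3,13,6,18,1
17,73,M,L,24,2,4,47,54,,,0
18,41,M,R,27,11,4,9,18,,,0
19,46,M,R,20,3,1,57,66,,,0
20,67,M,R,28,3,4,56,63,57,66,0
21,68,F,L,14,2,4,57,62,57,66,0
22,41,F,R,25,15,5,24,49,38,62,0
23,50,M,L,17,7,4,7,32,27,47,1
24,31,M,L,23,2,4,57,63,57,65,0
25,63,M,R,24,7,4,4,12,22,39,1
26,66,M,L,20,7,4,3,24,38,59,0
27,60,M,L,17,6,4,3,26,28,49,1
28,75,F,L,15,8,4,38,43,57,63,0
29,70,M,R,19,3,4,6,32,48,47,0
30,44,F,R,23,3,4,56,60,57,64,0
31,56,F,R,18,1,3,57,64,57,66,0
32,63,M,R,28,2,3,32,53,52,57,1
33,62,F,L,26,5,3,57,61,57,66,1
34,59,M,R,20,3,4,3,8,8,18,1
35,61,M,R,28,12,4,20,40,56,54,1
36,51,F,L,10,2,3,34,52,,,0
37,60,M,L,22,2,3,54,65,57,66,1
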