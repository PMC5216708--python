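patient_id,age,initial_dimensions_cm,residual_dimensions_cm,bts_percent,cellularity,pathology_override,response
1,55,5.4 x 5.0 x 2.3,No residual,100,none,,Responder
2,53,7.4 x 7.0,7 x 5 x 3,5,low,,Responder
3,41,5.3 x 4.4 x 4.7,2.7 x 2.5 x 2.4,49,high,,Non-Responder
4,65,10.0 x 10.0,1.6 x 0.8 x 0.5,84,none,,Responder
5,50,4.0 x 5.0,No residual,100,none,,Responder
6,33,3.0 x 3.0,1.4,53,none,,Responder
7,33,5.4 x 5.0 x 8.0,No residual,100,none,,Responder
8,48,4.9 x 4.9 x 4.1,1.4 x 1 x 1,71,none,,Responder
9,36,4.4 x 3.9 x 5.8,11.4,-97,none,,Non-Responder
10,40,4.4 x 3.4,No residual,100,none,,Responder
11,62,12.0 x 14.0,No residual,100,none,,Responder
12,59,6 x 2.3 x 4.3,2.6 x 2.5 x 2.5,57,none,,Responder
13,53,8.4 x 9.4 x 12.7,whole breast,0,none,,Non-Responder
14,48,7 x 9.0,5,44,none,Non-Responder,Non-Responder
15,50,13.0 x 11.0,4,69,none,,Responder
16,49,7.1 x 5.5 x 8.9,No residual,100,none,,Responder
17,40,3 x 2.4 x 3.0,No residual,100,none,,Responder
18,56,2.4 x 2.7 x 3.2,0.2 x 0.2,93,none,,Responder
19,49,2.4 x 2.8 x 1.4,1.4 x 2.4 x 1.4,96,none,,Responder
20,47,5.2 x 4.0 x 4.0,6.5,-25,none,,Non-Responder
21,52,4.1 x 3.0 x 2.5,No residual,100,none,,Responder
22,44,9.9 x 4.5 x 9.7,2 x 1 x 1; 1.6 x 1 x 0.5,64,none,,Responder
23,38,9.0 x 6.6 x 6.0,2.9 x 2 x 1.5; 2 x 1.5 x 1,46,none,,Responder
24,58,1.9 x 1.4 x 1.6,No residual,100,none,,Responder
25,35,5.9,No residual,100,none,,Responder
26,38,8.0 x 8.0,No residual,100,none,,Responder
27,47,8.0 x 10.0,12.5 x 4.5 x 3.5,-25,none,,Non-Responder
28,57,7.9 x 4.1 x 5.5,No residual,100,none,,Responder
29,47,6.3 x 4.1 x 7.4,No residual,100,none,,Responder
30,55,6.6 x 12.8 x 6.8,17,-33,low,,Responder
31,32,6.0 x 7.0 x 3.0,7.4,-6,low,,Responder
32,38,2.3 x 2.5 x 2.5; 1.0 x 1.0 x 0.7,2.8 x 3 x 2.3; 1.5 x 1.6 x 1.1,-31,none,,Non-Responder
33,45,6.5 x 5.0,2.8; 2,26,none,,Non-Responder
34,55,10 x 5 x 10.5,No residual,92,none,,Responder
35,59,8.0 x 5.7 x 3.0,No residual,100,none,,Responder
36,37,2.5 x 2.0,2.2 x 1.5 x 1.1,12,none,,Non-Responder
37,50,9.0 x 7.0 x 3.0,1.2,87,none,,Responder
38,54,3.6 x 3.6 x 2.3,5.5,-139,low,,Responder
39,55,1.6 x 1.2,1.2 x 0.9 x 0.7,25,none,,Non-Responder
40,50,7.3 x 2.5 x 7.3,2.1,71,none,,Responder
41,55,3.3 x 3.4 x 3.4,1.8,47,none,,Responder
42,44,3.0 x 3.5 x 1.5,No residual,100,none,,Responder
43,60,8.7 x 9.0 x 5.2,8.0 x 5.0 x 4.5; 3.0 x 2.5 x 1.7,-22,none,,Non-Responder
44,64,6.4 x 3.2 x 8.7,19,-197,none,,Non-Responder
45,67,3.2 x 8.7,3.2 x 3 x 1.8,63,none,,Responder
46,52,2.6 x 1.2 x 1.6,2.5 x 0.4 x 0.4,4,low,,Responder
47,47,8.0 x 7.0,4.5 x 3.1 x 2.9,44,none,,Responder
48,56,10.0 x 10.0,8.4 x 5.1 x 2.8,16,low,,Responder
49,45,2.3 x 2.0,No residual,100,none,,Responder
50,59,4.9 x 2.1 x 1.4,2.8 x 2.5 x 1.5,43,none,,Responder
51,66,3.5 x 5.2 x 2.1,4 x 3,23,none,,Non-Responder
52,49,1.8 x 2.1 x 2.1,No residual,100,none,,Responder
53,39,6.3,1.7 x 1.5 x 1,37,none,,Responder
54,62,4.4 x 6.3 x 3.3,12.6 x 6 x 3,-100,none,,Non-Responder
55,58,5.2 x 5.2 x 4.4,3.4,35,none,,Responder
56,58,2.3 x 4.0 x 2.3; 1.6 x 1.8 x 1.6,No residual,100,none,,Responder
57,45,2.7 x 3.2 x 2.0,3,6,none,,Non-Responder
58,29,4.2 x 2.9 x 2.7,4,0,none,,Non-Responder
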