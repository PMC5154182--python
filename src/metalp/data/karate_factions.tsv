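1	mr_hi
2	mr_hi
3	mr_hi
4	mr_hi
5	mr_hi
6	mr_hi
7	mr_hi
8	mr_hi
9	mr_hi
10	officer
11	mr_hi
12	mr_hi
13	mr_hi
14	mr_hi
15	officer
16	officer
17	mr_hi
18	mr_hi
19	officer
20	mr_hi
21	officer
22	mr_hi
23	officer
24	officer
25	officer
26	officer
27	officer
28	officer
29	officer
30	officer
31	officer
32	officer
33	officer
34	officer
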