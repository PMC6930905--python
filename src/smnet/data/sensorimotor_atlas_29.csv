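roi,x,y,z,region,side,brodmann
1,-7,-52,61,Precuneus,L,BA5
2,-14,-18,40,,L,
3,0,-15,47,Middle cingulum,L,
4,10,-2,45,Middle cingulum,R,
5,-7,-21,65,Paracentral lobule,L,BA4
6,-7,-33,72,Paracentral lobule,L,BA4
7,13,-33,75,Postcentral gyrus,R,BA4
8,-54,-23,43,Supramarginal gyrus,L,BA3
9,29,-17,71,Precentral gyrus,R,BA6
10,10,-46,73,Precuneus,R,BA5
11,-23,-30,72,Postcentral gyrus,L,BA4
12,-40,-19,54,Postcentral gyrus,L,BA4
13,29,-39,59,Postcentral gyrus,R,BA2
14,50,-20,42,Postcentral gyrus,R,BA3
15,-38,-27,69,Postcentral gyrus,L,BA4
16,20,-29,60,Precentral gyrus,R,BA3
17,44,-8,57,Precentral gyrus,R,BA6
18,-29,-43,61,Postcentral gyrus,L,
19,10,-17,74,Supplementary motor area,R,BA6
20,22,-42,69,Postcentral gyrus,R,
21,-45,-32,47,Postcentral gyrus,L,BA2
22,-21,-31,61,Postcentral gyrus,L,BA3
23,-13,-17,75,Paracentral lobule,L,BA6
24,42,-20,55,Postcentral gyrus,R,BA4
25,-38,-15,69,Precentral gyrus,L,BA6
26,-16,-46,73,Parietal superior,L,BA5
27,2,-28,60,Paracentral lobule,R,BA4
28,3,-17,58,Supplementary motor area,R,BA6
29,38,-17,45,Precentral gyrus,R,BA4
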