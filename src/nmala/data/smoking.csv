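study,treatment,responders,sampleSize
1,1,9,140
1,3,23,140
1,4,10,138
2,2,11,78
2,3,12,85
2,4,29,170
3,1,79,702
3,2,77,694
4,1,18,671
4,2,21,535
5,1,8,116
5,2,19,149
6,1,75,731
6,3,363,714
7,1,2,106
7,3,9,205
8,1,58,549
8,3,237,1561
9,1,0,33
9,3,9,48
10,1,3,100
10,3,31,98
11,1,1,31
11,3,26,95
12,1,6,39
12,3,17,77
13,1,64,642
13,3,107,761
14,1,5,62
14,3,8,90
15,1,20,234
15,3,34,237
16,1,95,1107
16,3,143,1031
17,1,15,187
17,3,36,504
18,1,78,584
18,3,73,675
19,1,69,1177
19,3,54,888
20,1,0,20
20,4,9,20
21,2,20,49
21,3,16,43
22,2,7,66
22,4,32,127
23,3,12,76
23,4,20,74
24,3,9,55
24,4,3,26
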