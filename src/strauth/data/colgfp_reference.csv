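marker,Col-GFP HSC
1-1,16
1-2,19
2-1,15
3-2,14
4-2,20.3
5-5,17
6-4,18
6-7,17
7-1,"26.2,27.2"
8-1,16
9-2,18
11-2,16
12-1,17
13-1,17
15-3,22.3
17-2,15
18-3,"16,17"
19-2,13
X-1,27
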