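marker,Col-GFP HSC,AT-3,YUMMER1.7-H2B-GFP5,DC2.4,MS1,YUMM1.7,MCA-205,MLTC-1
1-1,16,16,"16,17",17,17,"16,17",16,16
1-2,19,19,19,19,19,19,19,"19,20"
2-1,15,16,"16,17",16,16,16,16,16
3-2,14,14,14,14,14,14,"13,14","14,15"
4-2,20.3,20.3,20.3,21.3,20.3,20.3,20.3,"20.3,21.3"
5-5,17,17,17,17,17,17,17,17
6-4,18,"18,19",18,18,18,18,18,18
6-7,17,15,17,17,"16,17",17,"14,15",16
7-1,"26.2,27.2","26.2,27.2",27.2,"26.2,27.2",26.2,27,26.2,26.2
8-1,16,16,16,16,16,16,16,16
11-2,16,16,16,16,16,16,16,16
12-1,17,"17,18",17,17,17,17,"17,18",17
13-1,17,17,17,17,17,17,17,17
15-3,22.3,22.3,22.3,"22.3,23.3",22.3,22.3,22.3,22.3
17-2,15,15,16,16,"15,16,17",16,15,15
18-3,"16,17",16,16,16,16,16,16,16
19-2,13,13,13,13,13,13,"13,14",13
X-1,27,27,27,27,27,27,27,28
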