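marker,chromosome,range_min,range_max,fwd_primer,rev_primer
1-1,1,10,19,CCCTTCACTCCTTCATTCCA,TGAGCCTAAGGACCTGGACA
1-2,1,12,30.1,TCTTTAAAAATCAAACAGGCAAA,GGGGAGGTTGGGGTGTATAA
2-1,2,8,17.1,ACAACTTCAAACTTTGCTGGAA,TCCTGCTTAGCTTGTCATTTCC
3-2,3,9,25,TGAGCTACCATGTGGGTACA,CACACACACACACAAAGATGGA
4-2,4,13,23.3,AAGCTTCTCTGGCCATTTGA,TTCATAAACTTCAAGCAATGACA
5-5,5,11,22,CGTTTTACCTGGCTGACACA,TGGTTTAAAACTCAATACCAAACAA
6-4,6,12.2,21,TTTGCAACAGCTCAGTTTCC,AATCGCTGGCAGATCTTAGG
6-7,6,11,26,AGTCCACCCAGTGCATTCTC,CATGTGGCTGGTATGCTGTT
7-1,7,19.2,33.2,ACACCAGTTGGGGACTAGGA,AACTGGTGCTGGGTCTGAAC
8-1,8,6,19,AGTAATATCCTGGTCCTGGCC,GAGCTCACTATGTAGCTATTGGA
9-2,9,7.1,19,GGATTGCCAAGAATTTGAGG,TCCTGAGTTGTGGACAGGGTTA
11-2,11,12,26.2,AAGGCAGGGGAATTCACAGT,TCTCACCATTGCAGTCCTGA
12-1,12,15,24.1,TTTCAAAATTGTCATTGAACACA,TGGTCCTTCAGTATCATCCTTG
13-1,13,11,20.1,AACTCCCACTGCTTCTTGGT,GCCAAAGTAAACCCTTCTCCC
15-3,15,12,31.3,TCTGGGCGTGTCTGTCATAA,AGGCTATCTAAACTTGACATGCT
17-2,17,11,22,CTCTTCTCCATCCGTCCATC,ATGGCTCTTGCCACAAATCT
18-3,18,13,28,TCTTTCTCCTTTTGTGTCATGC,GCTAAATAACTAAGCAAGTGAACAGA
19-2,19,10,16,AGGCTAGCACTGTTCCTTGT,ACTCAGCACCTTCCATCCTG
X-1,X,15.2,37,AACAAAAATGTCCCTCAATGC,AAGGTATATATCAAGATGGCATTATCA
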