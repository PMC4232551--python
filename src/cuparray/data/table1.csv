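strain,repeat_type,unit_kb,ecoRI_frag_kb,southern_copies,deepseq_copies,cu_inhib_mM,ploidy
S288c,1,2.0,30.8,14,,2,haploid
W303-1A,1,2.0,31.3,14,,1.8,haploid
YJM189,2,1.8,23.3,11,6,0.8,diploid
YJM972,2,1.8,18.7,8,10,1,diploid
YJM996,2,1.8,25.4,12,12,1.4,diploid
YJM789,3,1.2,11.6,7,,0.4,haploid
YJM693,3,1.2,19.3,13,15,1.8,diploid
YJM1549,3,1.2,24.4,18,18,1.0,diploid
YJM271,4,1.9,20.7,9,8,0.3,diploid
YJM1307,4,1.9,15.5,6,4,0.3,diploid
YJM456,5,1.6,19.8,10,5,1.2,diploid
YJM969,5,1.6,8.5,3,4,0.2,diploid
YJM978,5,1.6,6.5,2,2,0.1,diploid
DTY3,none,,5.2,1,,<0.1,haploid
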