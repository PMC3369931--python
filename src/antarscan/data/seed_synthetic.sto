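# STOCKHOLM 1.0
seed01        CACATTGGTGTGTTCGA-------GGCATCGGCGCC
seed02        CACATCGGTGTGGTCGGC------GGCATCGGCGCC
seed03        GACATCGGTGTTAGCGATA-----GACATCGGCGTC
seed04        CACATCGTTGTGGAGCCCCG----GGCATCGGCGCC
seed05        TACATTGACGTAGATCCACTC---GGCATCGTCGCC
seed06        CACATCGGTGTGGGACGTGACC--CGCAACGGTGCG
seed07        CACATCGAAGTGGGACTGTGGTG-GGCATCGGCGCC
seed08        CACATCGGTGTGTGTCTTGGGCCCGTCAGCGGCGAC
seed09        CACATCGGTGTGCGCCC-------GCCATCGGTGGC
seed10        GACATCGGTGTCTAGTCC------GACAGGGGCGTC
seed11        CACATAGGTGTGAGTATCA-----GGCATCGCCGCC
seed12        CACATCGGTGTGTCATCTAG----GGCATCGTCGCT
seed13        CACATCGGTGTGGTGTTTGTA---AGCATCGGCGCT
seed14        CACATCGGTGTGCGTACATTTA--GGCATCGGCGCC
seed15        CACACCGGTGTGGAGCAATTAGA-GGCAGCGGCGCT
seed16        CACATCGGTGTGCTCGATAGGAGAGGCATAGTCGCT
seed17        CACATCGCTGTGCTCAC-------GGCATCGGCGCC
#=GC SS_cons  <<<......>>>............(((......)))
//
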