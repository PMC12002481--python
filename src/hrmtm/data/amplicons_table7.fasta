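>UPA99|Navicula_sp.
CCTCTTATGCTTTACACTCTAGATACGATTTCTACCCGTTCAGAGGAAACTTTGTACGTTTCC
>UPA99|Odontella_sp.
CCTTTATGCCTTTATACTCTAGATACGATTTCTATCCGTTCAGAGGAAACCTTTGTACGTTTCC
>UPA99|Skeletonema_sp.
TTATGCCTTTCACTCTAGATACGATTTCTACCCGTTCAGAGGATACCTTTGTACGTTTCC
>UPA99|Chaetoceros_sp.
CCTTTATGCCTTTACACTCTAGATACGATTTCTACCCGTTCAGAGGAAACCTTTGTACGTTTCC
>UPA99|Nitzschia_sp.
CTCTTATGCCTTTACACTCTAGATACGATTTCTACACGTTCAGAGGAAACCTTTGTACGTTTCC
>18S-V7|Navicula_sp.
TGTTTTCCTTGTGAAGGCAGGCACTTCTTAGAGGGACAATTGGTGTTTAGCCAATGGAAGTGGGAGGCAATAACAGGTCTGTGATGCC
>18S-V7|Odontella_sp.
CCGCGGATGATCTTTCATTGGCGAGAGCTTCTTAGAGGGACGACCGTCTACTAGACGGAGGAAGATAGGGGCAATAACAGGTCTGTGATGCC
>18S-V7|Skeletonema_sp.
CGCGATGGCTTTTCATTGGCGAGGTCTTCTTAGAGGGACGTTCATTCTACAAGATGAAGGAAGATGGCGGCAATAACAGGTCTGTGATGCC
>18S-V7|Chaetoceros_sp.
CGATGACTTTTCATTGGCGATGGTTTCTTAGAGGGACATGTAGTACAAAGCTACAGGAAGATTGGGGCAATAACAGGTCTGTGATGCC
>18S-V7|Nitzschia_sp.
GAGTGAGTTTTCACTGGGTGAAGCTTCTTAGAGGGACGTGCATTCTATTAGATGCAGGAAGATAGGGGCAATAACAGGTCTGTGATGCC
>ND|Navicula_sp.
ATCGAGGTTTAAGGTGGTTTAGACTTCTTAAAAGATGATGAGAACATTAACTCTCAACCATTCATGCGTTGGAGAGAA
>ND|Odontella_sp.
AATGAGGTTTAAGGTGGTTTAGACTTCTTAAAAGATGATGAAAACATTAACTCTCAACCATTCATGCGTTGGAGAGAA
>ND|Skeletonema_sp.
ATGACGTTTAAAGGTGGTTTAGACTTCTTAAAGGATGATGAAAATATTAACTCTCAACCATTCATGCGTTGGAGAGAA
>ND|Chaetoceros_sp.
TTTGAGTTTAAAGGTGGTTTAGACTTCTTAAAAGACGATGAGAACATCAATTCTCAACCATTCATGCGTTGGAGAGAA
>ND|Nitzschia_sp.
ATGAGGTTTAAAGGTGGTTTAGACTTCTTAAAAGATGATGAAAACATTAACTCTCAACCATTCATGCGTTGGAGAGAA
>Primer1|Navicula_sp.
TATTCAGCTCATAGCGTATATTAAAGTTGTTGCAGTTAAAAAGCTCGTAGTTGGATTTGTGGCATTGGTTGTGGCGTCCATTGATTTGGTTTTGCTGCGATCGTGCCATCCTTGGGTGGATTTTGTGTGGCATTAGGTTGTCGTGCAGG
>Primer1|Odontella_sp.
TATTCAGCTCATAGCGTATATTAAAGTTGTTGCAGTTAAAAAGCTCGTAGTTGGATATCTGGTGGGAGCAATGGGTCTCGCGCTTAGCGCGGGTACTTCAGTTGACTCCGGCCATCCTCGGGGAGAGCCCGTCTGGCATTAGGTTGTCGTGCAGG
>Primer1|Skeletonema_sp.
TCAGCTCATAGCGTATATTAAAGTTGTTGCAGTTAAAAAGCTCGTAGTTGGATTTCTGGCAGGAGTGACTGACCACAAACTCTGTTTGTGAGTTGTGTCATTCTGGCCATCCTTGGTAAGATCCTTTTTGGCATTAGGTTGTCGTGCAGG
>Primer1|Chaetoceros_sp.
TATTCAGCTCATAGCGTATATTAAAGTTGTTGCAGTTAAAAAGCTCGTAGTTGGATTTGTGGTGCGACGGATCGGTCCGACCTTTGGTGGGTACTCGATGTTGTCGCGCCATCCTTGAGTGGTTCGTCCTGGCATTAGGTTGTCGTGCAGG
>Primer1|Nitzschia_sp.
TATTCAGCTCATAGCGTATATTAAAGTTGTTGCAGTTAAAAAGCTCGTAGTTGGATTTGTGGCTGTCGATAGCGGCCTGTCACTTAGTGTCAGTGTTTGCTGTCGTCGCCATCCTTGGGTGGAGCCTGTGTGGCATTAGGTTGTCGTGCAGG
>psaA-2|Navicula_sp.
CGGTCCAGCTGTTATAAATCAGTCCATACAACTGTCCATGTTGCTGTAGAAGATTCACCTGCTACTGCTGCAGCAGCTTCTACTGGATCTACACCTGGTTGTGGTGTGATACGGA
>psaA-2|Odontella_sp.
CGCTCCAGCTGTTATAAATCTGTCCAAACAACAGTCCAAGTAGCTGTTGAAGATTCACCAGCTACTGCAGCTGCAGCTTCTACTGGATCTACACCTGGTTGTGGTGTGATACGGA
>psaA-2|Skeletonema_sp.
CGCTCCAGCTGTTATAAATCTGTCCATACAACAGTCCAAGTTGCAGTTGAAGATTCACCTGCTACAGCAGCAGCAGCTTCTACTGGATCTACACCTGGTTGTGGTGTGATACGGA
>psaA-2|Chaetoceros_sp.
CGTTCCACGCTGTTATAAATCTGTCCAAACAACAGTCCATGTTGCTGTTGAAGATTCACCTGCTACAGCAGCGGCAGCTTCTACTGGATCAACACCTGGTTGTGGTGTGATACGGA
>psaA-2|Nitzschia_sp.
CGGTCCAGCTGTTATAAATCAGTCCATACAACTGTCCAAGTTGCTGTAGAAGATTCACCAGCTACTGCTGCTGCAGCTTCTACTGGATCTACACCTGGTTGTGGTGTGATACGGA
>Dia18S|Navicula_sp.
TGTGGCGTCCATTGATTTGGTTTTGCTGCGATCGTGCCATCCTTGGGTGGATTTTGTGTGGCATTAGGTTGTCGTGCAGGGGATGCCCATCCTTTACA
>Dia18S|Skeletonema_sp.
ACTGACCACAACTCTGTTTGTGAGTTGTGTCATTCTGGCCATCCTTGGTAAGATCCTTTTTGGCATTAAGTTGTCGGGAAGGGGATGCCCATCCTTTACA
>Dia18S|Nitzschia_sp.
GTCGATAGCGGCTGTCACTTAGTGTCAGTGTTTGCTGTCGTCGCCATCCTTGGGTGGAGCCTGTGTGGCATTAGGTTGTCGTGCAGGGGATGCCCATCCTTTACA
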