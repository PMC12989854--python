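>T01
ATCGACTCGAATTCGCGTGTCCGTAATGCACAGCCCCTCCACGAC---GGTCCATTCCCTCCCTGGCCTAATACGCTTTC
CATCAAGTTCGAGGATGGCCTAACCATGTCCAGGCCTGAAGTGTCCTGTACCATAGTGGGCACCTCACAAGGGGGCGATG
TCTTCACTTGGACTATGCGCTAA
>T02
ATCGATTCGAATTCACGTGTCCGTAATGCACAGCCCCTCCACGAC---GGCCCATTCCCTCCCTGGCCTAATACGCTTTC
CATCAAGTTCGAGGATGGCCTAACCATGTCCAGGCCTGAAGTGTCCAGTACCATAGTGGGCACCTCACAAGGGGGCGATG
CCTTCACTTGGACTATGCGCTAA
>T03
ATCGATTCGAATTCACGTGTCCGTAATGCACAGCCCCTCCACGAC---GGCCCATTCCCTCCCTGGCCTAATACGCTTTC
CATCAAGTTCGAGGATGGCCTAACCATGTCCAGGCCTGAAGTGTCCAGTACCATAGTGGGCACCTCACAAGGGGGCGATG
CCTTCACTTGGACTATGCGCTAA
>T04
ATCGATTCGAATTCACGTGTCCGTAATGCTCAGCCCCTCCACGAC---GGCCTATTCCCTCCTTGGCCTAATACGCTTTC
CATCAAGTTCGAGGATGGCCTATCCATGTCCAGGCCTGAAGTGTCCTGTACCATAGTGGGCACCTCACAAGGGGGCGATG
CCTTCACTTGGACTATGCGCTAA
>T05
ATCGATTCGAATTCACGTGTCCGTAATGCACAGCCCCTCCACGAC---GGTCCATTCCCACCCTGGCCCAATACGCTTTC
CATCAAGTTCGAGGATGGCCTAACCATGTCCGGGCCTGAAGTGTCCTGTACCATAGTGGGCACCTCACAAGGGGGCGACG
CCTTCACTTGGACTATGCGCTAA
>T06
ATCGATTCGAATTCACGTGTCCGTAATGCACAGCCCCTCCACGAC---GGTCCATTCCCACCCTGGCCCATTACGCTTTC
CATCAAGTTCGAGGATGGCCTAACCATGTCCAGGCCTGAAGTGTCCTGTACCATAGTGGGCACTTCACAAGGGGGCGACG
CCTTCACTTGGACTATGCGCTAA
>T07
ATCGATTCGAATTCACGTGTCCGTAATGCACAGCCCCTCCACGACCAAGGTCCATTCCCTCCCTGGCCCAATACGCTTTC
CATCAAGTTCGAGGATGGCCTTACCATGTCTAGGCCTGAAGTGTCCTGTACCATAGTGGGCACCTCACAAGGGGGGGACG
CCTTCACTTGGACTATGCGCTAA
>T08
ATCGATTCGAATTCACGTGTCCGTAATGCACAGCCACTCCACGACCAAGGTCCATTCCCCCCCTGGCCCAATACGCTGTT
CATCAAGTTCGAGGATGGCTTAACCATGTCCAGGCCTGAAGTGTCCTGTACCATAGTGGGCACCTCGCAAGGGCGCGACG
CCTTCACTTGGACTATGCACTAA
>T09
ATCGATTCGAATTCACGTGTCCGGAATGCACAGCCTCTCCACGACCAAGGTCCATTCCCTCCCTGGCCCAATACGCTGTC
CATCAAGTTCGAGGATGGCTTAACCATGTCCAGGCCTGCAGTGTCCTGTACCATAGTGGGCACCTCACAAGGGCGCGGCG
CCTTCACTTGGACTATGCACTAA
>T10
ATCGATTCGAATTCACGTGTCCGGAATGCACAGCCACTCCACGACCAAGGTCCATTCCCTCCCTGGCCCAATACGCTGTC
CATCAAGTTCGAGGATGGCTTAACCATGTCCAGGCCTGAAGTGTCCTGTACCATAGTGGGCACCTCACAAGGGCGCGGCG
CCTTCACTTGGACCATGCACTAA
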