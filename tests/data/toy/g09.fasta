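>T01
CGTCGACCGCTTGCACGAACGATACTGACGCCGCTTAAACGTAGCAGTGTTAACAAACCTAATGGTACCTATAGCGCAGG
TGGCAGTCCGACGGATTTGGGGGTCCCAGCGACTACAGCCATGGAGCGGGAAGGCGTATTCCTCAACCACTTTCACGAAG
CATCCACCACACCCGGCGCGTAA
>T02
CGTCGACCGCTTGCACGAACGATACTGACGCCACTTAAACGTAGCAGTGTTAATAAACCGAATGGTACCTATAGCGCAGG
TGGCAGTGCGACGGATTTGGGGGTCCCAGCGACTACAGCCATGGAGCGGGAAGGCGTGTTCCTCAACCACTTTCACGAAG
CATCCACCACACCCGGCGCGTAA
>T03
CGTCGACCGCTTGCACGAACGATACTGACGCCGCTTAAACGTAGCAGTGTTAACAAACCGAATGGTACCTATAGCGCAGG
TGGCAGTGCGACGGATTTGGGGGTTCCAGCGACTACAGCCATGGAGCGGGAAGGCGTGTTCCTCAATCACTTTCACGAAG
CATCCACCACACCCGGTGCGTAA
>T04
CGTCGACCGCTTGCACGAACGATACTGACGCCGCTTAAACGTAGCAATGTTAACAAACCTAATGGTGCCTATAGCGCAGG
TGGCAGTGCGACGGATTTGGGGGTCCCAGCGACTACAGCCATGGAGCGGGAAGGCGTGTTCCTCAACCACTTTCACGAAG
CATTCACCACACCTGGCGCGTAA
>T05
CGTCGACCGCTTGCACGAACGATACTGACGCCGCTTAAACGTAGGAGTGTTAACAAACCTAATGGTACCTATAGCGCAGG
TGGCAGTGCGGCGGATTCGGGGGTCCCAGCGACTACAGCCATGGAGCGGGAAGGCGTGTTCCTCAACCACTTTCACGAAG
CATCCACCACACCCGGCGCGTAA
>T06
CGTCGACCGCTTGCACGAACGATACTGACGCCGCTTAAACGTAGGAGTGTTAACAAACCTAATGGTACCTATAGCGCAGG
TGGCAGTGCGGCGGATTTGGGGGTCCCAGCGACTACAGCCATGGAGCGGGAAGGCGTGTTCCTCAACCACTTTCACGAAG
CATCCACCACACCCGGCGCGTAA
>T07
CGTCGACCGCTTGCACGAACGATACTGAGGCCGCTTAAACGTAGGAGTGTTAACAAACCTAACGGTACCTATAGCGCAGG
TGGCAGTGCGGCGGATTTGGGGGTCCCAGCGACTACAGCCATAGAGCGGGAAGGCGTGTTCCTCAACCACTTTCACGAAG
CATCCACCCCACCCGGCGCGTAA
>T08
CGTCGACCGTTTGCACGAACCATTCTAACGCCGCTGAAACGCAGAAGTGTTAACAAACCTAATGGTACCTATGGCGCAGG
AGGGAGTGCGGCGGATTTGGGGGTGCCAGCGACAACAGCCATGGAGCGGGAAGGCGTGTTCCTCAACCACTTTCACGAAG
CATCCACCACACCCGGTGTGTAA
>T09
CGTCGACCGCTTGCACGAACGATTCTCACGCCGCTGAAACGCAGAAGTGTTAACAAACCTAATGGTACCTATGGCGCAGG
TGGCAGTGCGGCGGATTTGGGGGTCCCAGCGACAACAGCCATGGAGCGGGATGGCGTGTTCCTTAACCACTTTCACGAAG
CATCCACCACACCCGGCGCGTAA
>T10
CGTCGACCGCTTGCACGAACGATTCTCACGCCGCTGAAACGCAGAAGTGTTAACAAACCTAATGGTACCTACGGCGCAGG
TGGCAGTGCGGCGGATTTGGGGGTCCCAGCGACAACAGCCATGGAGCGGGATGGCGTGTTCCTTAATCACTTTCACGAAG
CATCCACCACACCCGGCGCGTAA
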