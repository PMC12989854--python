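>T01
CCAAAATTGATACTTGCTGGACTACCACCGGGTGCTCCTCGCTGGCTGATAGGGAGATCGAGCAAGCGTACCCTTACGTG
GGATCGAGTCCGCGATAGACTTTGTAGGAGCCCCACCCCGCACTCTCCTTTAATGCGAGGAGTACGTACTTGTGTTCGTG
CGACAACTAGGTGTCCATCGTAA
>T02
CCAAAATTGATACTTGCTGGTCTACCACCGGGTGCTCCTCGCTGGCTAATAGGGAGATCGAGCAAGCGTACCCTTACGTG
GGATCGAGTCCGCGATAGCCTTTGTAGGAGCCCCACCCCGCACTCTCCTTTGATGCGAGGAGTACGTACTTGTATTCGTG
TGACAACTAGGTGTCCATCGTAA
>T03
CCAAAATTGATACTTGCTGGTCTACCACCGGGTGCTCCTCGCTGGCTAATAGGGAGATCGGGCAAGCGTACCCTTACGTG
GGATCGAGTCCGCGATAGCCTCTGTAGGAGTCCCACCCCGCACTCTCCTTTGATGCGAGGAGTACGTACTTGTATTCGTG
TGACAACTAGGTGTCCATCGTAA
>T04
CCAAAATTGATACTTGCTGGTCTACCACCGGGTGCTCCTCGCTGGCTAATAGGGAGATTGAGCAAGCGTACCCTTACGTG
GGATCGAGTCCGCGATAGCCTTTGTAGGAGCCCCACCCCGCACTCTCCTTTGATGCGAGGAGTACGTACTTGTGTTCGTG
CGACAACTAGGTGTCCATTGTAA
>T05
CCGAAATTAATACTTGCTGGTCTACCACCGGGTGCTCTTCGCTGGCTAATGGGGAGATCGAGCAAGCGTACCCTTACGTG
GGATCGAGTCCGCGATAGCCTTTGCAGGAGCCCCACCCCCCACTCTCCCTTGATGCGAGGAGTACGTACTTGTGTTCGTG
CGACAACTAGGTGTCCATCGTAA
>T06
CCAAAATTAATACTTGCTGGTCTACCACCGGGTGCTCTTCGCTGGCTAATGGGGAGATCGAGCAAGCGTACCCTTACGTG
GGATCGAGTCCGCGATAGCCTTTGCAGGAGCCCCACCCCCCACTCTCCCTTGATGCGAGGAGTACGTACTTGTGTTCGTG
CGACAACTAGGTGTCCATCGTAA
>T07
CCGAAATTAATACTTGCTGGTCTACCACCGGGTGCTCCTCGCTGGCTAATGGGGAGATCGAGCAAGCGTACCCTTACGTG
GGATCGAGTCCGCGATAGCCTTTGTAGGAGCCCCACCCCCCACTCTCCTTTGATGCGAGGAGTTCGTACGTGTGTTCGTG
CGACAACTAGGTGTCCATCGTAA
>T08
CCGAAATTGATACTTGCCCGTCTACCACCGGGAGCTCCTCGCTGGCTAATGGGGAGATCGAGCAAGCGTACCCTTACGTG
GGATCGAGTCCGCGATAGCCTTTGCAGGAGCGCCCCCCCCCACTCTCCTTTGATCCGAGGAGTACATACGTGTGTTCGTG
CGACAACTAGGTATCCTCCGTAA
>T09
CCGAAATTGATACTTGCCCGTCTACCACCGGGAGCTCCTCGCTGGCTAATGGGGAGATCGAGCAAGCGTACCCTTACGTG
GGATCGAATCCGCGATAGCCTTTGCAGGAGCGCCCCCCCCCACTCTCCTTTGATGCGAGGAGTACATACGTGTGTTCGTG
CGACAACTAGGTATCCTTCGTAA
>T10
CCGAAATTGATACTTGCCCGTCTACCACCGGGAGCTCCTCGCTGGCTAATGGGGAGATCGAGCAAGCGTACCCTTACGTG
GGATCGAGTCCGCGATAGCCTTTGCAGGAGCGCCCCCCCCCACTCTCCTTTGATGCGAGGAGTACATACGTGTGTTCGTG
CGACAACTAGGTATCCTTCGTAA
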