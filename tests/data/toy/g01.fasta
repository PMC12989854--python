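>T01
TTTATCCGTCAAGTAGGTGTGATTCGAGAAACAGTACCCTTAAACTCCAAGAATACCGTGGCCAGAAGCCAGGAGTCCAC
GGATCCCCACCAGTCTGGTATTAATCGATACTACCGGGGGTATAGTGGATTTTCCATGAGTCGTTTACAATTGACCAAGT
CTAAGTGTCGGTTGAGCAGTTAA
>T02
TTTATCCGTGAAGTAGATGTGATTCGAGGAACAGTACCCTTAAACTCCAAGAATACCGTGGTCAGAAGCCAGGAGTCCAC
GGATCCGGACCAGTCTGGGATTAATCGATACTACCGGGGGTATAGTGGATTTTCCATGAGTTGTTTACAAGTGACCAAGT
CTAAGTGTCGGTTGAGCAGTTAA
>T03
TTTATCCGTCAAGTAGATGTAATTCGAGGAACAGTACCCTTAAACTCCAAGAATACCGTGGTCAGAAGCCAGGAGTCCCC
GGATCCGCACCAGTCTGGGATTAATCGATACTACCGGGGGTATAGTGGATTTTCCATGAGTTGTTTACAAGTGACCAAGT
CTAAGTGTCGGTTGAGCAGTTAA
>T04
TTTATCCGTCAAGTAGATGTGATTCAAGGAACAGTACCCTTAAACTCCAAGAATACCGTGGTCAGAAGCCAGGAGTCCAC
GGATCCCCACCAGTCTGGGATTAATCGATACTACCGGGGGTATAGTGGATTTTCCATGAGTTGTTTACAATTGACCAAAT
CTAAGTGTCGGTTGAGCAGTTAA
>T05
TTCATCCGTCAGGTAGATGTGATTCGAGGAACAGTGCCCTTAAACTCCAAGAATAGCGTGGTCAGAAGCCAGGAGTCCAC
GGACCCCCACCAGTCTGGGATTAATCGATACTACCGGGGGTATAGTGGATTTTCCATGAGTTGTTTGCAATTGACCAAAT
CTAAGTGTCGGTTGAGCAGTTAA
>T06
TTCATCCGTCAGGTAGATGTGATTCGCGGAACAGTGCCCTTAAACTCCAAGAATAGCGTGGTCAGAAGCCAGGAGTCCAC
GGATCCCCACCAGTCTGGGATTAATAGATACTACCGGGGGTATAGTGGATTTTCCATGAGTTGTTTGCAATTGACCAAAT
CTAAGTGTCGGTTGAGCAGTTAA
>T07
TTCATCCGTCAAGTAGATGTGATTCGAGGAACAGTACCCTTAAACTCCAAGAATAGCGTGGTCAGAAGCCAGGAGCCCAC
GGATCCCCACCAGTCTGGGATTAACCGATACTACCGGGGGTTTAGTGGATTTTCCATGAGTTGTTTACAATTGACCAAAT
CTAAGTGTCGGTTGAGCAGTTAA
>T08
TTCATCCGTCAAGTAGACGTGATTCGAGGAACAGTGCACTTGAACTCCCAGAATACCGTGGTCAGTAGTCAGGAGTCCAC
GGATCCTCACCAGTCTGGGCTTAATCGACACTACCGGGGTTATAATGGATTTTCTATGAGTTGTTTACAATTGACCAAAT
CTAAGTGTCGATTAAGCAGTTAA
>T09
TTCATCCGTCAAGTAGATGTGATTCGAGGAACAGTGCACTTGAATCCCCAGAATACCGTGGTCAGTAGCCAGGAGTCCAC
GGATCCTCACCAGTCTGGCGTAAATCGATACTACCGGGGTTATAGTGGATTTTCCATGAGTTGTTTACAATTGACGAAAT
CTAAATGTCGACTAAGCAGTTAA
>T10
TTCATCCGTCAAGTAGATGTGATTCGAGGAACAGTGCACTTGAATCCCCAGAATACCGTGGTCAGTAGCCAGGAGTCCAC
TGATCCTCACCAGTCTGGCGTAAATCGATACTACCGGGGTTATAGTGGATTTTCCATGAGTTGTTTACAACTGACGAAAT
CTAAATGTCGATTAAGCAGTTAA
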