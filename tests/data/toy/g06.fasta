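>T01
CAGTGCAACGAAAGCCAGTTCGGTCAGAGGGCCAGAAGACCGGGCCATGGCCTAGGGGACRCTAGAAGTCACCTTTCCAA
TTTGGGGATGTGCGAGAAACCAAGGCGTCAAGAGACTGCCCGTGAGGTACTAGATGGAAGTGGCCTAATCTGTCGTAATC
AACATCGCAGTAGATCCCGGTAA
>T02
CAGTGCAACGAAAGCCAGTTCGGTCAGAGGGCCAGAAGACCGGGCCATGGCCTAGGGGACRCTAGGAGTCACCTTTCTAA
TTTGGGTATGTGCGAGAAACCAAGGCGTCAAGAGACTGCCCGTGAGGTACTAGATGGAAGTGGCCTAATCTGTCGTAATC
AACATCGCAGTAGATCCCGGTAA
>T03
CAGTGCAACGAAAGCCAGTTCGGTCAGAGGGCCAGAAGACCGGGCCATGGCCTAGGGGACRCTAGGAGTCACCTTTCTAA
TTTGGGTATGTGCGAGAAACCAAGGCGTCAAGAGACTGCCCGTGAGGTACTAGATGGAAGTGGCCTAATCTGTCGTAATC
AACATCGCAGTAGATCCCGGTAA
>T04
CAGTGCAACGAAAGCCAGTTCGGTCAGAGGGCCAGACGACCGGGCCATGGCCTATGGGACCCTAGGAGTCACCTTTCTAA
TTTGGGGATGTGCGAGAAACCAAGGCGTCAAGAGACTGCCCGTGAGGTACTAGATGGAAGTGGCCTAATCTGTCGTAATC
AACATCGTAGTAGATCCCGGTAA
>T05
CAGTGCAACGAAAGCCAGTTCGGTCAGAGAGCCAGAAGACCGGGCCACGGCCTGGGGGACCCTAGAAGTCACCTTTCTAA
TTTGGGGATGTGCGAGAAACCAAGGCGTCAAGAGACTGCCCGTGAGGTGCTAGATGGAAGTGGCCTAATCTGTCGTAATC
AACATCGAAGTAGATCCCGGTAA
>T06
CAGTGCAACGAAAGCCAGTTCGGTCAGAGAGCCAGAAGACCGGGCCACGGCCTGGGGGACCCTAGAAGTCACCTTTCTAA
TTTGGGGATGTGCGAGAAACCAAGGCGTCAAGAGACTGCCCGTGAGGTGCTAGATGGAAGTGGCCTAATCTGTCGTAATC
AACATCGAAGTAGATCCCGGTAA
>T07
CAGTGCAACGAAAGCCAGTTCGGTCAGAGGGCCAGAAGACCGGGTCATGGCCTGGGGGACCCTAGAAGTCACCTTTCTAA
TTTGGGGATGTGCGAGAAACCAAGGCGTCAAGAGACTGCCCGTGAGGTGCTAGATGGAAGTAGCCTAATCTGTCGTAATC
AACATCGCAGTAGATCCCGGTAA
>T08
CAGTGCAACGAAAGCCAGTTCGGGCAGAGGGCCAGAAGACCGAGCCATGGCCTGGGGGACCCTAGAAGCCACCTTTCTAA
TTTGGGGATGTGCGAGAAACCAAGGCTTCAAGAGACTGCCCGTGAGGTGCTAGATGGAAGCGGCCTAATCTGCCGTAATC
AACATCGCAGTAGATCCCGGTAA
>T09
CAGCGCAACGAAATCCAGTTCGGTCAGCGGGCCAGAAGACCGAGCCATGGGCTGGGGGACTCTAGGAGCCACCTTTCTAA
TTTGGGGATGTGCGAGAAACCAAGGCTTCAAGAGACTGCCCGCGAGGTTCTAGATGGAAGCGGCCTAATCTGCCGCAATC
AACATCGCAGTAGATCTCGATAA
>T10
CAGCGCAACGAAATCCAGTTCGGTCAGAGGGCCAGAAGACCGAGCCATGGGCTGGGGCACTCTAGGAGCCAGCTTTCTAA
TTTGGGGATGTGCGAGAAACCAACGCTTCAAGAGACTGCCCGCGAGGTGCTAGATGGAAGCGGCCTAATCTGCCGCAATC
AACATCGCAGTAGATCCCGATAA
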