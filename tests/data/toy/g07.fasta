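>T01
AATAACGCGCTCATGTTGCTAGCTATCAGGGTGGATGAGATGGCAATGTTAGATGCGGGCTGTTTCGAACGAGTGTTAAC
CTTGTGCAGACACAAGATATACACCAGCAAGACTGGGCTCGGTCATTCCTCAGATGAAAAGGCTGGGGGTTTATCGAAAC
GCCACTCATCATCTGTCGGCTAA
>T02
AATAACGCGCTCATGTTGCTAGCTATCAGGGTGGATGAGATGGCAATGTTGGATGCGAGCTGTTTCGAACGAGTGTTAAC
CTTGAGCAGACACAAGATATACACCAGCAAGACTGGGCTCGGTCATTCCTCAGATGAAAAGGCTGGGGGTTTATCGAAAC
GCCACTCATCATCTGTCGGCTAA
>T03
AATAACGCGCTCATGTTGCTAGCTATCAGGGTGGATGAGATGGCAATGTTGGATGCGAGCTGTTTCGAACGAGTGTTAAC
CTTGAGCAGACACAAGATATACACCAGCAAGACTGGGCTCGGTCATTCCTCAGATGAAAAGGCTGGGGGTTTATCGAAAC
GCCACTCATCATCTGTCGGCTAA
>T04
AATAACGCGCTCATGTTGCTAGCTATCAGGGTGGATGAGATGGCAATGTTGGATGCGAGCTGTTTCGAACGAGTGTTAAC
CTTGAGCAGAAACAAGATATACACCAGCAAGACTGGGCTCGGTCATTCCTCAGATGAAAAGGCTGGGGGTTTATCGAAAC
GCCACTCATCATCTGTCGGCTAA
>T05
AATAACGCGCTCATGTTGCTAGCTATCAGGGTGGTTGAGATGGCAAGGTTGGATGCGAGCTGTTTCGAACGAGTGTTAAC
CTTGAGCAGACAGAAGATATACACCAGCAAGACTGGGCTCGGTCATTCTTCAGATGAGAGGGCTGGGGGTTTATCGAAAC
GGTACTCATCATCTGTTGGCTAA
>T06
AATAACGCGCTCATGTTGCTAGCTATCAGGGTGGTTGAGTTGGCAAGGTTGGATGCGAGCTGTTTCGAACGAGTGTTAAC
CTTGAGCAGACAGAAGGTATACACCAGCAAGACTGGGCTCGGTCATTCTTCAGATGAGAAGGCTGGGGGTTTATCGAAAC
GGCACTCATCATCTGTCGGCTAA
>T07
AATAACGCGCTCATGTTGCTAGCTATCAGGGTGGTTGAGATGGCGAGGTTGGATGCGAGCTGTTTCGAACGAGTGTTAAC
CTTGAGCAGACACAAGATATACACCAGCAAGACTGGGCTCGGTCATTCCTCAGATGAAAAGGCTGGGGGTCTATCGAAAC
GGCACTCATCATCTGTCGGCTAA
>T08
AATAACGCGCTCATGTTGCTAGCTATCCGGGTGGTTGAGATGGTAAGGTTTGATGCGAGCTGTTTCGAACGAGTATTAAC
CCTGAGCCGTCACAAGATATACACTAGCAGGGCTGGCCTGGGCCATTCCTCAGATGAAAAGGCTGGGGGTTTATCGAAAC
GACACTCTTTATCTGTCGGCTAA
>T09
AATAACGCGCTCATGTTGCTAGCTATTCGGGTTGTTGAGATGGCAAGGTTGGATGCGAGCTGTTTCGAACGAGTGTTAAC
CCTTAGCAGACACAAGATATACACCAGCAGGGCTGGCCTGGGCCATTCCTCAGATGAAAAGGCTGGGGGTTTATCGAAAC
GACACTCATCATCCGTCGGCTAA
>T10
AATAACGCGCTCATGTTGCTAGCTATCCGGGTTGTTGAGATGGCAAGGTTGGATGCAAGCTGTTTCGAAAGAGTGTTAAC
CCTTAGCAGACACAAGATATACACCAGCAGGGCTGGCCTGGGCCATTCCTCAGATGAAAAGGCTGGGGGTTTATCGAAAC
GACTCTCATCATCCGTCGGCTAA
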