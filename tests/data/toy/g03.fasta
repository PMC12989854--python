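>T01
GCCTTGTCGGACTGATGCATGGCCTAAAGGAAGTTGCTTCATACATGCATATCAAGTCCACCCCGCCAGGCTCCGTCGAC
ACTTACGGAACCCCTCTGCCAGTAGATTTTCGTCTAATGCTACAATACCACGGTCCCAACTCGGAATCGTGCCTCAGCTT
GATGCTGGGATCTAGGGGAATGTAA
>T02
GCCTTGTCGGACTGATGCATGGCCTAAAGGAAGTTGCTTCATACATGCATATCAAGTCCACCCCGCCGGGCTCCGTCGAC
ACGTACGGGACCCCTCTGCCAGTAGATTTTCGTCTAATGCTACAATACCACGGTCCCAACTCGGAATCGTGCCTCAGCTT
GATGCTGGGATCTAGGGGTATGTAA
>T03
GCCTTGTCGGACTGATGCATGGCCTAAAGGAAGTTGCTTCATACATGCATATCAAGTCCACCCCGCCAGGCTCCGTCGAC
ACGTACGGGACCCCTCTGCCAGTAGATTTTCGTCTAATGCTACAATACCACGGTCCCAACTCGGAATCGTGCCTCAGCTT
GATGCTGGGATCTAGGGGTATGTAA
>T04
GCCTTGTCGGACTGATGCATGGCCTAAAGGAAGTTGCTTCATACATGCATATCAAGTCCACCCCGCCAGGCTCCGTCGAC
ACTTACGGGACCCCTCTGCCAGTAGATTTTCGTCTAATGCTACAATACCACGGTCCCAACTCGGAATCGTGCCTCAGCTT
GATGCTGGGATCTAGGGGAATGTAA
>T05
GCCTTGCCGGACTGATGCATGGCCTGAAGGAAGTTGCTTCATACATGCATATCAAGTCGACCCCGCCAGGCTCCGTCGAC
ACTTACGGGACCCCTTTGCCAGTAGATTTTCGTTTAATGCTACAATACCACGGGCCCAACTCGGAATCGTGCCTCAGCTT
GATGCTGGGATCTAGGGGAATGTAA
>T06
GCCTTGTCGGACTGATGCATGGCCTGAAGGAAGTTGCTTCATACATGCATATCAAGTCGACCCCGCCAGGCTCCGTCGAC
ACTTACGGGACCCCTTTGCCAGTAGATTTTCGTTTAATGCTACAATACCACGGGCCCAACTCGGAATCGTGCCTCAGCTT
GATGCTGGGATCTAGGGGAATGTAA
>T07
GCCTTGTCGGACTGATGCATGGCCTAAAGGAAGTTGCTGCATACATGCATATCAAGTCCACCCCGCCAGGCTCCGTCGAC
ACTTATGGGACCCCTTTGCCAGTAGATTTTCGTTTAATGCTGCAATACCACGGGCCCAACTCGGAATCGTGCCTCAGCTT
GATGCTGGGATCTAGGGGAATGTAA
>T08
GCCTTGTCGGGCTGATGCATGGCCTAAAGGAAGTTGCTTCATACATGCATATCAAGTCCACCCCGCCAGCCTCGGTCGAC
ACTTACGGGACGCCTTTGCCAGTAGATTTACGTTTAATGCTTCAATACCACGGTCCCAACTCGGAATCGTGCCTCAGCTT
GAAGCTGGGATCTAGGGGAATGTAA
>T09
GCCTTGTCGGACTCATGCATGGCCTAAAGGAAGTTGCTTCATACTTGCATACCAAGTCCACCCCGCCAGGCTCGGTCGAC
ACCTACGGGACGCCTTTGCCAGTAGATTTACGTTTAATGCTTCAATACCACGGCCCCAACTCGGAATCGTGCCTCAGCTT
GATGCTTGGATCTAGGGGAATGTAA
>T10
GCCTTGTCGGACTCATGCATGGCCTAAAGGAAGTTGCTTCATACATGCATACCAAGTCCACCCCGCCAGGCTCGGTCGAC
ACCTACGGGACGCCTTTGCCAGTAGATTTACGTTTAATGCTTCAATACCACGGCCCCAACTCGGAATCGTGCCTCAGCTT
GATGCTTGGATCTAGGGGAATGTAA
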