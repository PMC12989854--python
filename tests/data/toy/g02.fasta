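>T01
GCCACCCGTCGCTTCGCATCTGACCACCTGTCCCACTGCCTTCCACGGTGCAACGAAATGCGATATCGCAACGTCAATCC
CGTTCCCTCAAGTGGGGGTTACCAATGCATCTCGGCCAGGCTACAATCTAAGCTACACCGCACTAATCGACCCAATCGCG
TCGCGGGGTCATACATCCAGCTAA
>T02
GCCACCCGTCGCTTCGCATCTGACCACCTGTCCCACTGCCTTCCACGGTGCAACGAAATGCGATATCGCAACGTCAATCC
CGTTCCCGCAAGTGGGGGTTACCAATGCATCTCGGCCAGGCTACAATCTAAGCTACACCGCACTAATCGACCCAATCGCG
TCGCGGGGTCATACATCCAGCTAA
>T03
GCCACCCGTCGCTTCGCATCTGACCACCTGTCCCACTGCCTTCCACGGTGCAACGAAATGCGATATCGCAACGTCAATCC
CGTTCCCGCAAGTGGGGGTTACCAATGCATCTCGGCCAGGCTACAATCTAAGCTACACCGCACTAATCGACCCAATCGCG
TCGCGGGGTCATACATCCAGCTAA
>T04
GCCACCCGTCGCTTCGCACCTGACCACCTGTCCCACTGCCTTCCACGGTGAAACGAAATGCGATATCGCAACGTCAATCC
CGTTCCCTCAAGTGGGGGTTACCAATGCATCTCGGCCAGGCTACAATCTAAGCTACACCGCACTAATCGACCCAATCGCG
TCGCGGGGTCATACATCCAGCTAA
>T05
GCCACCCGTCGCTTCGGATCTGACCACCTGTCCCACTGCCTTCCACGGTGCAACGAAATGCGATATCGCAACGTCAATCC
CGTTCCCTCAAGTGGGGGTGACCAATGCATCTCGGCCAGGCTACAATCTAAGCTACACCGCATTAATCGACCCAATCGCG
TCGCGGGGTCATACATCTAGCTAA
>T06
GCCACCCGTCGCTTCGGATCTGACCACCTGTCCCACCGCCTTCCACGGTGCAACGAAATGCGATATCGCAACGTCAATCC
CGTTCCCTCAAGTGGGGGTGACCAATGCATCTCGGCCAGGCTACAATCTAAGCTACACCGCATTAATCGACCCAATCGCG
TCGCGGGGTCATACATCCAGCTAA
>T07
GCCACCCGTCGCCTCGCATCTGACCACCTGTCCCACTGCCTTCCACGGTGCAACGAAATGCGATATCGCAACGTCAATCC
CGTTCCCTCAAGTAGGGGTTACCAATGCATCTCGGCCAGGCTACAATCTAAGCAACACCGCATTAATCGACCCAATCGCG
TCGCGGGGTCATACATCCAGCTAA
>T08
GCCGCCGGTCGCTTCGCATTTGACAACCTGTCCCACTGCCTTCCACGGTGCAACGAAATGCGATATCGCAACGTCAATCC
CCTTCCCACAAGTAGGGGTTACCAACGCATCTCGGCCAGGCTACAATCTAAGCTATACCGCATTAATGGCCCTAATCGCG
TCACGGGGTCATACATCCAGCTAA
>T09
GTCACCCGTGGCTTCGCATTTGACAACCTGTCCCACCGCCATCCACGGTGCTACGATATGCGATATCGGAACGTCAATCC
CCTTCCCACAAGTAGGGGTTACCAACGCATCCCGGCCAGGCTACAATCTAAGCTACACCGCATTAATCGCCCTAATCGCG
TCGCGGGGTCATACATCCAGCTAA
>T10
GCCACCCGTGGCTTCACATTTGACAACCTGTCCCACCGCCATACACGGTGCTACGAAATGCGATATCGCAACGTCAATCC
CCTTCCCACAAGTAGGGGTTACCAACGCATCTCGGCCAGGCTATAATCTAAGCTACACCGCATTAATCGCCCTAATCGCG
TCGCGGGGTCATACATCCAGCTAA
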