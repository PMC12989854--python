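>T01
GGCGAGACGCTACGTAGCCTAATAGGATTGCCACCCTGCTCTCAGGATAGCCACGGACGTCTTAGTATTAGTCACATATC
GGGATTGCTTTGGGTCAGATATTGTAGTAACCAATCGTTAGAAGTCTCCTATAGCCTACTCGAGTTGTTGCAGTTTACCG
GCCGCCCTTTAACAATCTACTAA
>T02
GGCGAGACGCTACGAAGTCTAATAGGATTGCCACCCTGCTCTCAGGATAGCCACGGAAGTCCTAGTATTAGTCACATATC
GGGATTGCTTTGGGTCAGATATTGTGGCAACCAATCGTTAGAAGTCTCCTATAGCCTACTCGAGTTGTTGCAGTTTACCG
GCCGCCCTTTAACAATCTACTAA
>T03
GGCGAGACGCTACGAAGTCTAATAGGATTGCCACCCTGCTCTCAGGATAGCCACGGAAGTCCTAGTATTAGTCACATATC
GGGATTGCTTTGGGTCAGATATTGTGGCAACCAATCGTTAGAAGTCTCCTATAGCCTACTCGAGTTGTTGCAGTTTACCG
GCCGCCCTTTAACAATCTACTAA
>T04
GGCGAGACGTTACGTAGTCTAATAGGATTGCCACCCTGCTCTCAGGATAGCCACGGAAGTCCTAGTATTAGTCACATATC
GGGATTGCTTTGGGTCAGATATTGTGGTAACCACTCGTTAGAAGTCTCCTATAGCCTACTCGAGTTGTTGCAGTTTACCG
GCCGCCCTTTAACAATCTACTAA
>T05
GGCGAGACGTTACGTAGTCTAATAGGATTGCCACCCTGCTCCCAAGATAGCCATGGAAGTCCTAGTATTAGTCACATATC
GGGATTGCTTTGGGTCAGATATTGTGGTAACCAATCGTTAGCAGTCTCTTATAGCCTACTCGAATTGTTGCAGTTTACCG
GCCGCCCTTTAACAATATACTAA
>T06
GGCGAGACGTTACGTAGTCTAATAGGATTGCCACCCTGCTCCCAAGATAGCCATGGAAGTCCTAGTATTAGTCACATATC
CGGATTGCTTTGGGTCAGATATTGTGGTAACCAATCGTTAGCAGTCTCTTATAGCCTACTCGAATTATTGCAGTTTACCG
GCCGCCCTTTAACAATATACTAA
>T07
GGCGAGACGCTACGTAGTCTAATAGGATTGCCACCCTGCTCTCAGGATAGCCAGGGAAGTCCTAGTATTAGTCACATATC
GGGATTGCTTTGGGTCAGATATTGTGGTAACCAATCGTTAGAAGTCTCTTATAGCCTACTCGAGTTGTTGCAGTTTACCG
GCCGCCCATTAACAATCTACTAA
>T08
GGCGAGACGCTACGTAGTCTAATAGGATTGCCACCCTGCTCTCAGGATCGTCATGGAAGTCCTAGCATTAGTCAAATGTC
GGGATTGCGTTGGGTCAGATATTGTGGTAACCAATCGTTAGAAGTCTCTTATAGCCTACTAGAGTTGTTGCAGTTTACCG
GCCGCCCTTTAACAATCTACTAA
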