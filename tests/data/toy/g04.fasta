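>T01
CGCACATCGGAAGGTTTCCGATACTACCTTTGATTTGGCTGTCGCCGTACAAACCCTATAGCCTTGTGGCGCACGAAGGC
ACCGATGAGACTGACAAGCCTGTGTACAGGGGGCGTGTCAAAACAACTTACCGAGGCCTCACATCTGTACGGTCTCAACA
CGGATGTAAGTGCAGTTGAGTAA
>T02
CGCACCTCGGAAGGTTTCCGATACTACCTTTTCTTTGGCTGTCGCCGTACAAACCCTATAGCCTTGTGGCGCACGAAGGC
ACCGATGAGACTGACAAGCCTGTGTACAGGGGGCGTGTCAAAACAACTTACCGAGGCCTCACATCTGTACGGTCTCAACA
CGGATGTAAGTGCAGTAGAGTAA
>T03
CGCACCTCGGAAGGTTTCCGATACTACCTTTTCTTTGGCTGTCGCCGTACAAACCCTATAGCCTTGTGGCGCACGAAGGC
ACCGATGAGACTGACAAGCCTGTGTACAGGGGGCGTGTCAAAACAACTTACCGAGGCCTCACATCTGTACGGTCTCAACA
CGGATGTAAGTGCAGTAGAGTAA
>T04
CGCACCTCGGAAGGTTTCCGATACTACCTTTTCTTTGGCTGTCGCCGTACAAACCCTATAGCCTTGTGGCGCACGAAGGC
ACCAATGAGACTGACAAGCCTGTGTACAGGGGGCGTGTCAAAACAACTTACCGAGGCCTCACATCTCTACGGTCTCAACA
CGGATGTAAGTGCAGTAGAGTAA
>T05
CGCACATCGGAAGGTTTCCGATACTACCTTTTCTTTGGCTGTCGCCGTACAAACCCTATAGCCTTGTGGCGCACGAAGGC
ACCGATGACACTGACATGCCTGTGTACAGGGGGCGTGTCAAAACAACTTACCGAGGCCTCACATCTGTACGGTCTCAACA
CAGATGTAAGTGCAGTAGAGTAA
>T06
CGCACATCGGAAGGTTTCCGATACTACCTTTTCTTTGGCTGTCGCCGTACAAACCCTATAGCCTTGTGGCGCACGAAGGC
ACCGATGACACTGACATGCCTGTGTACAGGGGGCGTGTCAAAACAACTTACCGAGGCCTCACATCTGTACGGTCTCAACA
CAGATGTAAGTGCAGTAGAGTAA
>T07
CGCACATCGGAAGGTTTCCGATACTACCTTTTTTTTGGCTGTCGCCGTACAAACCCTATACCCTTGTGGCGCACGAAGGC
ACCGATGAGACTGACATGCCTGTGTACAGGGGGCGTGTCAAAACAACTTACCGAGGCCTCACATCTGTACGGTCTCAACA
CAGATGTAAGTGCAGTGGAGTAA
>T08
CACACATCGGAAGGTTTCCGCTACTACCTTTTCTTTGGCTGTCGCCGTACAAACCCTCTAGCCTTGTGGCGCACGAAGGC
ACCGATGAGACTGACATGCCTGTGCACAGGGGGCGTGTCAAAACAACTTAATGAGGCTTCACATCTGTACGGTCTCAACA
CAGATGTAAGTTCCGTAGCGTAA
>T09
CGCACATCGGAAGGTTTCCGATACTACCTTTTCTTTGGCGGTCGCCGTACAAACCCTATAGGCTTGTGGCGCACGAAGGC
ACCGATCAGACTGACATGCTTGTGCACAGGGGGCGTGTCAAAACAACTTACCGAGGGCTCACATCTGTACGGTCCCAACA
CAGATGTAAGTTCCGTAGCGTAA
>T10
CGCACATCGGAAGGTTTCCGATACTACCTTTTCTTTGGCTGTCGCCGTACAAACCCTATAGGCTTGTGGCGCACGAAGGC
ACCGATCAGACTGACATGCTTGTGCACACGGGGCGTGTCAAAACAACTTACCGAGGGCTCACATCTGTACGGTCCCAACA
CAGATGTAAGTTCCGTAGCGTAA
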