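>T01
GAATTGAGACACAGCCGTTTCCCGCCCAAAGTGAAGCGCAGTCGTTTACTTATTATAGCAGCCCACGCAAGCAAATGTAG
AGTGCATGTGGAGGTTATTACACGGTTTCACTCGGCGCAACTATCCGCAAGCTTAAACATGGTGGCAATACCGATTACGT
ATCAACAGACGAAAAAAAAA
>T02
GAATTGAGACACAGCCGTTTCCCACCCAAAGTTAAGCGCATTCGTTTACTTATTATAGCAGCCCACGCAAGCAAATGTAG
AGTGCATGTGGAGGTTATTACACGGTTTCACTCGGCGCAACTATCCGCAAGCTTAAACATGGTGGCAATACCGATTACGT
ATCAACAGACGAAAAAAAAA
>T03
GAATTGAGACACAGCCGTTTCCCACCCAAAGTTAAGCGCATTCGTTTACTTATTATAGCAGCCCACGCAAGCAAATGTAG
AGTGCATGTGGAGGTTATTACACGGTTTCACTCGGCGCAACTATCCGCAAGCTTAAACATGGTGGCAATACCGATTACGT
ATCAACAGACGAAAAAAAAA
>T04
GAATTGAGACACAGCCGTTTCCCGCCCAAAGTTAAGCGCATTCGTTTACTTATTATAGCAGCCCACGCAAGCAAATGTAG
AGTGCATGTGGAGGTTATTACACGGTTTCACTCGGCGCAACTATCCGCAAGCTTAAACATGGTGGCAATACCGATTACGT
ATCAACAGACGAAAAAAAAA
>T05
GAATTGCGACACAGCCGTTTCCCGCCTAAAGTTAAGCGCATTCGATTACTTATTATAGCAGCCCACGCAAGCAAATGTAG
AGTGCATGTGGAGGTTATTACACGGTTTCACTCGGCGCAACTATCCGCAAGGTTAAACATGGTGGCAATACCGATTACGT
ATCAACAGACGAAAAAAAAA
>T06
GAATTGCGACACAGCCGTTTCCCGCCTAAAGTTAAGCGCATTCGATTACTTATTATAGCAGCCCACGCAAGCAAATGTAG
AGTGCATGTAGAGGTTATTACACGGTTTCACTCGGCGCAACTATCCGCAAGCTTAAACATGGTGGCAATACCGATTACGT
ATCAACAGACGAAAAAAAAA
>T07
GAATTGCGACACAGCCGTTTCCCGCCTAAAGTTAAGCGCATTCGACTACTTATTATAGCCGCCCACGCAAGCAAATGTAG
AGTGCATGTGGAGGTTATTACACGGTTTCACTCGGCGCAACTATCCGCAAGCCTAAACATGGTGGCAATACCGATTACGT
ATCAACAGGCGAAAAAAAAA
>T08
GAACTGCGACATAGCCGCTTCTTGCCGAAATTTAAGCGCATCCGATTACTTATTATAGCAGCCCACGCGAGCAAATGTAG
AGTGCATGTGGAGGTTATGACACGGTTTCACTCGGCGCACCTCTCCGCAAGCTTAAACATGGTAGCAATACCGATTACGT
ATCAACGGACGAAAAAAAAA
>T09
GAACTGCGACACACCCGCTTCTTGCCAAAAGTTAAACGCATTCGATTACTTATTATGGCGGCCCATGCAAGCAAATGTAG
AGTGCATGTGGAGGTTATTACACGGTTTCACTCGGCGCAACTATTCGCAAGTTTAAACATGGTAGCAATCCCGATTACGT
ATCAACGGACGAAAAAAAAA
>T10
GAACTGCGACACAGCCGCTTCTTGCCAAAAGTTAAACGCATTCGATTACTTATTATGGCGGCCCACGCAAGCAAATGTAG
AGTGCATGTGGAGGTTATTACACGGTTTCACTCGGCGCAACCATTCGCAAGTTTAAACATGGTAGCAATCCCGATTACGT
ATCAACGGACGAAAAAAAAA
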