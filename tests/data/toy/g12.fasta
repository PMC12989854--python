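>T01
GTTCTGATAAGATCCACGGCCAATGCGACAAATGGAAGTGTCATCACGGTAATGATCAGGCTGCTTGGTCAGGCCACATC
CGTCACTCGCCGCCATCGCCGTGCTGGCCGCTCCGCTAGATTCCCACCTGAGAGGTCAGAGAACAAAGCCTCCAGACAGT
TATTCGCAACGTCCCCAACATAA
>T02
GTTCTGATAAGATCCACGGCCAATGCGACAAATGGAAGTGTCATCACGGTAATGATCAGGCTGCTTGGTCAGGCCACATC
CGTCACTCGCCGCCATCGCCGTGCTGGCCGCTCCGCTAGATTCCCACCTGAGAGGTCAGAGAACAAAGCCTCCAGACAGT
TATTCGCAACGTCCCCAACATAA
>T03
GTTCTGATAAGATCCACGGCCAATGCGACAAATGGAAGTGTCATCACGGTAATGATCAGGCTGCTTGGTCAGGCCACATC
CGTCACTCGCCGCCATCGCCGTGCTGGCCGCTCCGCTAGATTCCCACCTGAGAGGTCAGAGAACAAAGCCTCCAGACAGT
TATTCGCAACGTCCCCAACATAA
>T04
GTTCTGATAAGATCCACGGCCAATGCGACAAATGGAAGTGTCATCACGGTAATGATCAGGCTGCTTGGTCAGGCCACATC
CGTCACTCGCCGCCATCGCCGTGCTGGCCGCTCCGCTAGATTCCCACCTGAGAGGTCAGAGAACAAAGCCTCCAGACAGT
TATTCGCAACGTCCCCAACATAA
>T05
GTTCTGATAAGATCCACGGCCAATGCGACAAATGGAAGTGTCATCACGGTAATGATCAGGCTGCTTGGTCAGGCCACATC
CGTCACTCGCCGCCATCGCCGTGCTGGCCGCTCCGCTAGATTCCCACCTGAGAGGTCAGAGAACAAAGCCTCCAGACAGT
TATTCGCAACGTCCCCAACATAA
>T06
GTTCTGATAAGATCCACGGCCAATGCGACAAATGGAAGTGTCATCACGGTAATGATCAGGCTGCTTGGTCAGGCCACATC
CGTCACTCGCCGCCATCGCCGTGCTGGCCGCTCCGCTAGATTCCCACCTGAGAGGTCAGAGAACAAAGCCTCCAGACAGT
TATTCGCAACGTCCCCAACATAA
>T07
GTTCTGATAAGATCCACGGCCAATGCGACAAATGGAAGTGTCATCACGGTAATGATCAGGCTGCTTGGTCAGGCCACATC
CGTCACTCGCCGCCATCGCCGTGCTGGCCGCTCCGCTAGATTCCCACCTGAGAGGTCAGAGAACAAAGCCTCCAGACAGT
TATTCGCAACGTCCCCAACATAA
>T08
GTTCTGATAAGATCCACGGCCAATGCGACAAATGGAAGTGTCATCACGGTAATGATCAGGCTGCTTGGTCAGGCCACATC
CGTCACTCGCCGCCATCGCCGTGCTGGCCGCTCCGCTAGATTCCCACCTGAGAGGTCAGAGAACAAAGCCTCCAGACAGT
TATTCGCAACGTCCCCAACATAA
>T09
GTTCTGATAAGATCCACGGCCAATGCGACAAATGGAAGTGTCATCACGGTAATGATCAGGCTGCTTGGTCAGGCCACATC
CGTCACTCGCCGCCATCGCCGTGCTGGCCGCTCCGCTAGATTCCCACCTGAGAGGTCAGAGAACAAAGCCTCCAGACAGT
TATTCGCAACGTCCCCAACATAA
>T10
GTTCTGATAAGATCCACGGCCAATGCGACAAATGGAAGTGTCATCACGGTAATGATCAGGCTGCTTGGTCAGGCCACATC
CGTCACTCGCCGCCATCGCCGTGCTGGCCGCTCCGCTAGATTCCCACCTGAGAGGTCAGAGAACAAAGCCTCCAGACAGT
TATTCGCAACGTCCCCAACATAA
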