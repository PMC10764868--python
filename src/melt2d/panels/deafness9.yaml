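name: deafness9
description: 'Nine-locus single-tube deafness hotspot panel (GJB2, SLC26A4, GJB3, MT-RNR1): each allele
  occupies one (fluorophore channel, tag-probe Tm) coordinate'
tolerance_c: 1.0
loci:
- gene: GJB2
  locus_id: c.235delC
  ploidy: diploid
- gene: GJB2
  locus_id: c.176-191del16
  ploidy: diploid
- gene: GJB2
  locus_id: c.299_300delAT
  ploidy: diploid
- gene: SLC26A4
  locus_id: c.919-2A>G
  ploidy: diploid
- gene: SLC26A4
  locus_id: c.2168A>G
  ploidy: diploid
- gene: SLC26A4
  locus_id: c.1229C>T
  ploidy: diploid
- gene: GJB3
  locus_id: c.538C>T
  ploidy: diploid
- gene: MT-RNR1
  locus_id: m.1494C>T
  ploidy: mitochondrial
- gene: MT-RNR1
  locus_id: m.1555A>G
  ploidy: mitochondrial
probes:
- channel: FAM
  label: carboxyfluorescein
  sequence: ccatctacactcccaaactaatcttttcttccttatctc
- channel: HEX
  label: hexachloro-fluorescein
  sequence: cctaatcatcaaccacttaccatcacttcacctatccat
- channel: Alexa568
  label: Alexa568
  sequence: cacctatccttctatcattcctttccattcaatactcct
coordinates:
- locus_id: c.235delC
  allele: wild
  channel: FAM
  tm_c: 64.4
- locus_id: c.235delC
  allele: mutant
  channel: HEX
  tm_c: 63.2
- locus_id: c.176-191del16
  allele: wild
  channel: FAM
  tm_c: 59.6
- locus_id: c.176-191del16
  allele: mutant
  channel: HEX
  tm_c: 59.6
- locus_id: c.299_300delAT
  allele: wild
  channel: FAM
  tm_c: 53.2
- locus_id: c.299_300delAT
  allele: mutant
  channel: HEX
  tm_c: 56.4
- locus_id: c.919-2A>G
  allele: wild
  channel: FAM
  tm_c: 66.8
- locus_id: c.919-2A>G
  allele: mutant
  channel: HEX
  tm_c: 67.2
- locus_id: c.2168A>G
  allele: wild
  channel: FAM
  tm_c: 41.2
- locus_id: c.2168A>G
  allele: mutant
  channel: Alexa568
  tm_c: 62.0
- locus_id: c.1229C>T
  allele: wild
  channel: FAM
  tm_c: 48.4
- locus_id: c.1229C>T
  allele: mutant
  channel: Alexa568
  tm_c: 66.0
- locus_id: c.538C>T
  allele: wild
  channel: FAM
  tm_c: 36.4
- locus_id: c.538C>T
  allele: mutant
  channel: Alexa568
  tm_c: 50.4
- locus_id: m.1494C>T
  allele: wild
  channel: HEX
  tm_c: 47.2
- locus_id: m.1494C>T
  allele: mutant
  channel: Alexa568
  tm_c: 41.6
- locus_id: m.1555A>G
  allele: wild
  channel: HEX
  tm_c: 42.4
- locus_id: m.1555A>G
  allele: mutant
  channel: Alexa568
  tm_c: 35.6
oligos:
- locus_id: c.919-2A>G
  allele: wild
  channel: FAM
  tag_sequence: ccatctacactcccaaactgatcttttcttccttatctc
  specific_primer: AAATGGCAGTAGCAATTATCGCCT
  reverse_primer: CCAATGGAGTTTTTAACATCTTTTG
- locus_id: c.235delC
  allele: wild
  channel: FAM
  tag_sequence: ccatctacactcccaaacgcttcttttcttccttatctc
  specific_primer: ACACGAAGATCAGCTGCACGG
  reverse_primer: CATCTCCCACATCCGGCTAT
- locus_id: c.176-191del16
  allele: wild
  channel: FAM
  tag_sequence: ccatctacactcccaaagctgcattttcttccttatctc
  specific_primer: GGAAGTAGTGATCGTAGCACACGTT
  reverse_primer: CGACTTTGTCTGCAACACCCT
- locus_id: c.299_300delAT
  allele: wild
  channel: FAM
  tag_sequence: ccatctacactcccagtgaggatgattcttccttatctc
  specific_primer: CCTTGATGAACTTCCTCTTCTTATCATG
  reverse_primer: CAGCGCTCCTAGTGGCCAT
- locus_id: c.1229C>T
  allele: wild
  channel: FAM
  tag_sequence: ccatctacactcctgtgagctaagacgcttccttatctc
  specific_primer: AGTGCTCTCCTGGACGGACG
  reverse_primer: GGATTCTTCTCTTGTTTTGTGGC
- locus_id: c.2168A>G
  allele: wild
  channel: FAM
  tag_sequence: ccatcttaggatccaaactaatcttttacggacaatctc
  specific_primer: AGGACACATTCTTTTTGACGGTACA
  reverse_primer: CTCTTGAGATTTCACTTGGTTCTGT
- locus_id: c.538C>T
  allele: wild
  channel: FAM
  tag_sequence: ccatcttgcactagaaactaatctttatgcgaacatctc
  specific_primer: ATCGTGGACTGCTACATGGCCC
  reverse_primer: GCCCACCATGAAGTAGGTGAAG
- locus_id: c.919-2A>G
  allele: mutant
  channel: HEX
  tag_sequence: cctaatcatcaaccacacgccatcacttcacctatccat
  specific_primer: TGAAATGGCAGTAGCAATTATAGTCC
  reverse_primer: CCAATGGAGTTTTTAACATCTTTTG
- locus_id: c.235delC
  allele: mutant
  channel: HEX
  tag_sequence: cctaatcatcaaccacgacagatcacttcacctatccat
  specific_primer: GACACGAAGATCAGCTGAAGGC
  reverse_primer: CATCTCCCACATCCGGCTAT
- locus_id: c.176-191del16
  allele: mutant
  channel: HEX
  tag_sequence: cctaatcatcaaccaccagatcgtacttcacctatccat
  specific_primer: GGGGAAGTAGTGATCGTACCTGG
  reverse_primer: CGACTTTGTCTGCAACACCCT
- locus_id: c.299_300delAT
  allele: mutant
  channel: HEX
  tag_sequence: cctaatcatcaaccacaattttaagattcacctatccat
  specific_primer: CCTTGATGAACTTCCTCTTCTACTCG
  reverse_primer: CAGCGCTCCTAGTGGCCAT
- locus_id: m.1494C>T
  allele: wild
  channel: HEX
  tag_sequence: cctaatcatcgttcacttaccatatagctcgacgtccat
  specific_primer: AATGTCCTTTGAAGTATACTTGAGCAGG
  reverse_primer: TGAAGCGCGTACACACCG
- locus_id: m.1555A>G
  allele: wild
  channel: HEX
  tag_sequence: cctaatcatcacgtacttaccgcgcgaagttaattccat
  specific_primer: CCAGTACACTTACCATGTTACGAATTGT
  reverse_primer: ACTAAAACCCCTACGCATTTATATAGAG
- locus_id: c.1229C>T
  allele: mutant
  channel: Alexa568
  tag_sequence: cacctatccttctatcatttctttccattcaatactcct
  specific_primer: AGTGCTCTCCTGGAAGGCCA
  reverse_primer: GGATTCTTCTCTTGTTTTGTGGC
- locus_id: c.2168A>G
  allele: mutant
  channel: Alexa568
  tag_sequence: cacctatccttctatcattgatttccattcaatactcct
  specific_primer: GACACATTCTTTTTGACGGGCCG
  reverse_primer: CTCTTGAGATTTCACTTGGTTCTGT
- locus_id: m.1494C>T
  allele: mutant
  channel: Alexa568
  tag_sequence: cacctatccttctaaatccaaaccatattcaatactcct
  specific_primer: AAATGTCCTTTGAAGTATACTTGACGAGA
  reverse_primer: TGAAGCGCGTACACACCG
- locus_id: m.1555A>G
  allele: mutant
  channel: Alexa568
  tag_sequence: cacctatccaggtatcattcctttgatcgagtcgctcct
  specific_primer: CAGTACACTTACCATGTTACGACGTGC
  reverse_primer: ACTAAAACCCCTACGCATTTATATAGAG
- locus_id: c.538C>T
  allele: mutant
  channel: Alexa568
  tag_sequence: cacctatatgcatatcattcctggtgtgctcatactcct
  specific_primer: CATCGTGGACTGCTACATTCCCT
  reverse_primer: GCCCACCATGAAGTAGGTGAAG
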