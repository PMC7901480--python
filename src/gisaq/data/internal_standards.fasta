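>IS1 472 bp synthetic internal standard, GC%=46.40
GTACTCCTACGGGAGGCAGCAGCCTTGCTAGGCATCGATGAAGAACGCAGCTTTTCACTACTATTAGTAC
TCACGACACAATACTACCACAGCCTTGTTTCGCCAGAATGCTAGTCAGCATATAGAAGAGCTCAAGGCAG
GTCAATTCGCATTGTCAGGGTTACATGAATGTTTGGCACTACCGACACGAACCTCAGTAAGCGTTCTTAC
TACCAGATGTCTGTGTCCGCGTGGTCAAAAGTGAGGTTTTCGTATTTGCTGCTCATCTATACTTTCACAA
TCTTAACCTGCACGGCAAAAAGATGCTTTTTATGGAGTTCGACAACGCAATAACGCGACGAATCTACGTC
ACAACGAGTATAGTAAAAACAAAATGCATATCAATAAGCGGAGGAGGAACCGTCCCCCAAGCGTTCAGGG
TGGGCTTTGCTACGACTTCCGAGTCCAAAGATTAGAAACCCTGGTAGTCCAC
>IS2 472 bp synthetic internal standard, GC%=46.20
GTACTCCTACGGGAGGCAGCAACTCCCTGTTGCATCGATGAAGAACGCAGCAAGAATGATGATAATCATG
AGTACTGTGCTAAGACGGTGTCGAAACAAAGCGGTCTTACGGTCAGTCGTATTTCCTCTCGAGTCTCGTC
CAGTTGAGCGTATCACTCTCAATGTACTAGCAAGCCAAGAAGGCTGTGCTTGGAGTCAATCTGATGTAGG
ATGATCTCCAGACACCAGGCCACTACTCTTCATACTTAAAGCATAAACGTCGAACAGTCATGAAAGTCTT
AGTACCGGACGTACCATTTTACTGTGAATATTACCTGAAGCTGTACCGTTATTGAGGAGCAAAGATGTAG
TACTGCTCTTATCATATTTGTATTGGCATATCAATAAGCGGAGGACCCACGCACCTGATCGCTCCTCGTT
TGCTTTTAAGGACCGGACGAACCACAGAGCATTAGAAACCCTGGTAGTCCAC
>IS3 472 bp synthetic internal standard, GC%=45.60
GTACTCCTACGGGAGGCAGCATACTGCGACCGCATCGATGAAGAACGCAGCCTCTAACTACTATCAATAC
CCATGACTTGACTCTGCTGCAGCTACGTATCGCCTGAAAACCAGTTAGTGTTAAGGAATGCTCTGACCAG
GACAACACACGTAGTGAAAGTTACATGTTCGTTGGGTTCTTCCGACTCGGATCTGAGTTGACCAATGACT
CACTTGAGATCTGAACCCTAGTGATGATAAATATGTATCTCGTTCACGCAGATTGCCAGCACTTTCAGAA
TCATGATGTGCATGGTAGAATGACTCTTATAACGAACTTCGACATGATAATATCCCCCCCTTTCAACTTC
TAGAGAAGAAAAGTATTGACATGAGGCATATCAATAAGCGGAGGATTCATCAGCTAACGTAACGGTTAGA
GGCTCGCTAAATCGCACTGTCGGCGTCCCTATTAGAAACCCTGGTAGTCCAC
>IS4 472 bp synthetic internal standard, GC%=45.40
GTACTCCTACGGGAGGCAGCATGGGTATTTTGCATCGATGAAGAACGCAGCCGTTCCCAGCACAACAGCC
AAAGAAGTTTCCAATTTTTTATTTCCGAATGACATGTGTCTCCTTGCGGGTAAATCGCCGACCGCAAAAC
TTAGGAGCCAGGGGAAACAGATAGGTCTAATTAACTTAAGGGAGTAAATCTTGGAATCGTTCAGTTGTAA
CTATATACTTACGCTGGAACTTCTCCGGCGAATTTTTACTGTCACCAACTACGAGATTTGAAGTAAACCA
ATTAAGCACATAGTCGCGCTATCCGACAATTTCCAAATTATAACATATCGTTCCATGAAGGCCAGAATTA
CTTACCGGCCCTTTCCATGCGTGCAGCATATCAATAAGCGGAGGAGCTGATCCGAGTCGAGTTAAAAACA
CCAGTACCCAAAACCAGGCGGGCTCGCCACATTAGAAACCCTGGTAGTCCAC
>IS5 472 bp synthetic internal standard, GC%=46.90
GTACTCCTACGGGAGGCAGCAGTCGGCTAATGCATCGATGAAGAACGCAGCCCATACCCTCCTACTTCCC
CGCTTATCTATCCGAAGAGAGAGTGTGCGATCCTCCGTTAAGATATTCTTACGTATGATATAGCTATGTA
TTTTGTAGAGGTAGCGAACGCGTTAAACATTTCACAGATAGTGGGGATTCGGGCAAAGGGCGTATAATTG
TGGACTAACATAGTCGTAAACTACGATGGTACCAACTCAATCTCAGCTCGTGCGCCTAAATAACGTACTC
ATCTCAACTGATTCTTGGCAATCTACGGAGCGACTTGATTATTAACAGTTGTCTAGCGAGTTCTAATCTT
TTACCAACATCGTAATAGCCTCCAAGCATATCAATAAGCGGAGGAATCCGCAGTGGCCGGTAGACACACG
TCCACCCCGCTGCTCTGTGACGGGGACTAAATTAGAAACCCTGGTAGTCCAC
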