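# Standard eight-locus grape phylloxera SSR panel.
#
# Locus names, master-mix groupings (MM1-MM4), dye pooling (FAM+PET and
# VIC+NED poolplexes), universal-tail length range (15-18 bp), the poly-A
# motif of Dvit5, and historic allele size ranges are the published panel
# design.  Primer sequences, exact tail lengths per dye, and the remaining
# repeat motifs are SYNTHETIC placeholders (the published appendix with the
# exact sequences is not redistributed here); they satisfy every stated
# constraint and are only used to build synthetic test constructs.
#
# historic_platform1 = false marks loci whose "Platform 1" entries in the
# reference genotype table are expected sizes from the original marker
# publication rather than measured polyacrylamide data; platform
# comparisons against polyacrylamide are not applicable for them.

[Dvit1]
forward_primer = "CGTGATTCCGGTTTGACACG"
reverse_primer = "AGCTCCTGCGAACTGTCACC"
tail_length = 15
motif = "AG"
dye = "PET"
size_range = [120, 145]
mix_group = "MM2"
historic_platform1 = true

[Dvit2]
forward_primer = "TATGGAAACCCACGAGGGAG"
reverse_primer = "TTAGAATCCGCGCTTTACCT"
tail_length = 17
motif = "AC"
dye = "NED"
size_range = [250, 295]
mix_group = "MM4"
historic_platform1 = true

[Dvit3]
forward_primer = "GTTGCGCATATTCCTGGAGT"
reverse_primer = "TGACGAGTTGCGTACATATT"
tail_length = 17
motif = "AT"
dye = "NED"
size_range = [165, 195]
mix_group = "MM4"
historic_platform1 = true

[Dvit4]
forward_primer = "ATCACGTGGCGTGTGCCACC"
reverse_primer = "TCCTCCTGAGACTACTTCAC"
tail_length = 18
motif = "CT"
dye = "FAM"
size_range = [148, 175]
mix_group = "MM1"
historic_platform1 = true

[Dvit5]
forward_primer = "TGCAACAAGTAGGTCGCTCT"
reverse_primer = "GCCGCCCGACCCAACCTACC"
tail_length = 16
motif = "A"
dye = "VIC"
size_range = [120, 150]
mix_group = "MM3"
historic_platform1 = true

[Dvit6]
forward_primer = "TAGAACCCCTAAGCCGATCG"
reverse_primer = "GGACGAGGAGTACCGGGTTG"
tail_length = 18
motif = "ATC"
dye = "FAM"
size_range = [190, 220]
mix_group = "MM1"
historic_platform1 = true

[DVSSR3]
forward_primer = "AAGAGAATCGACTTCGATCC"
reverse_primer = "CATATTCCCCAGAGAGTTCC"
tail_length = 15
motif = "AG"
dye = "PET"
size_range = [230, 290]
mix_group = "MM2"
historic_platform1 = false

[DVSSR4]
forward_primer = "GAGTGGTTCAATCGTTAGCT"
reverse_primer = "ATGGGGCGCTTCCTTTCGTA"
tail_length = 18
motif = "AC"
dye = "FAM"
size_range = [240, 260]
mix_group = "MM1"
historic_platform1 = false
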