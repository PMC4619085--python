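# Default Insert-1 template (synthetic).
#
# This is a constructed stand-in for the published 165-nt Insert-1 design,
# whose exact nucleotide sequence is not reproduced here. It satisfies every
# structural invariant of that design: five constant segments summing to
# 125 nt, so that adding two 20-nt targeting regions yields a 165-nt oligo;
# a central cassette carrying exactly one BsmBI site per strand (CGTCTC /
# GAGACG), oriented so that digestion excises both recognition sites; and no
# BsmBI site in any other segment. Segment order in the assembled oligo:
#   gibson5 | gRNA1 target (20 nt) | scaffold_frag | bsmbi_cassette |
#   gRNA2 target (20 nt) | h1_frag | gibson3
gibson5 = TATCTTGTGGAAAGGACGAAACACC
scaffold_frag = GTTTTAGAGCTAGAAATAGCAAGTT
bsmbi_cassette = ACCTAGAGACGTTCAGCATCGTCTCAGTTT
h1_frag = AATATTTGCATGTCGCTATGTGTTC
gibson3 = GGAAATCACCATAAACGTGA
t2_orientation = sense
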