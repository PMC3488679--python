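# Default tRNA-Leu (UAA) intron reference profile.
#
# SYNTHETIC reference: the conserved flank anchors, heptamer consensus
# patterns, indel-element catalogue and the position-71 offset below are an
# internally consistent synthetic stand-in for the published reference
# alignment, which is not redistributed here.  The synthetic sequence
# generator emits introns against this same profile, so every structural
# rule (repeat classes, indel tags, signature characters) is exercised end
# to end.  Edit or replace this file to annotate against a real reference.
name: default-synthetic

# conserved anchors flanking the P5b stem loop
p5b_flank5: GGCAGAGA
p5b_flank3: TCTCTGCC

# conserved anchors flanking the variable P6b stem loop
p6b_flank5: TCAGGACT
p6b_flank3: AGTCCTGA

# offset (nt) from the start of the p5b_flank5 match to the base mapped to
# reference coordinate 71; the signature character 71T is a T at this site
position71_offset: 14

# degenerate heptanucleotide repeat consensus patterns (IUPAC)
class1_consensus: ACCTAAY
class2_consensus: GGTTCRA

# a 7-mer window counts as a repeat unit when >= this many positions match
# the consensus (or its reverse complement, for the 3' arm of the hairpin)
repeat_match_threshold: 5

# non-repeat indel sequence elements with their insertion-point tags
indel_elements:
  "*": GATCGGCAA
  "**": CCGAGTT
  "***": TTACGGATC
  "^^": GGAACCTT
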