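# Default motif definitions for the RNA polymerase III type-1 (5S rRNA)
# internal control region: box A, intermediate element (IE) and box C.
#
# The motifs are taken as substrings of the bundled 5S rDNA reference below
# (a synthetic, human-like 5S rRNA gene sequence used only to define the
# default patterns; it is not a database record).  Coordinates are 0-based
# half-open on the reference; spacing ranges constrain the gap (in nt)
# between consecutive boxes in a scanned sequence.  Replace this file (or
# pass another via the API/CLI) to scan with organism-specific patterns.
reference_id: 5S_rDNA_synthetic_human_like
reference: GTCTACGGCCATACCACCCTGAACGCGCCCGATCTCGTCTGATCTCGGAAGCTAAGCAGGGTCGGGCCTGGTTAGTACTTGGATGGGAGACCGCCTGGGAATACCGGGTGCTGTAGGCTTT
box_a: [50, 64]
ie: [66, 72]
box_c: [79, 90]
gap_a_ie: [2, 10]
gap_ie_c: [5, 15]
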