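# Methods

This note documents the models, algorithms and numerical choices behind
`trimp3`, in the spirit of a methods supplement: what each stage assumes,
which parameters matter, and what the synthetic benchmark does and does not
demonstrate.

## The element model

A TRIM (terminal repeat retrotransposon in miniature) is modelled as

```
5'-[TSD] [LTR] [PBS ... PPT] [LTR] [TSD]-3'
```

* two **LTRs**, identical at insertion time, 80–400 bp here (observed TRIM
  LTRs run roughly 100–330 bp);
* a short non-coding **internal region** (50–700 bp) that begins, within
  its first 50 bp, with a **primer-binding site (PBS)** complementary to a
  cellular tRNA and ends, within 5 bp of the 3' LTR junction, with a
  purine-rich **polypurine tract (PPT)**;
* an exact 4–6 bp **target site duplication (TSD)** in the flanking host
  DNA, created at integration — target-derived, hence different at every
  copy;
* optionally, a small-RNA-derived **RNA polymerase III promoter** inside
  the LTRs: either the tRNA-type (type 2) box A + box B architecture
  (*Helenus*-like, class `TRIMp3_tRNA`) or the 5S-type (type 1)
  box A + IE + box C internal control region (*Ajax*/*Cassandra*-like,
  class `TRIMp3_5S`). TRIMs without such a promoter are canonical
  (`TRIMp2`).

A **solo LTR** is the single-LTR relic of recombination between the two
LTRs of an inserted copy; it keeps the copy's original TSD pair.

## Pairwise alignment

All alignment is affine-gap Smith–Waterman (and a free-end-gap variant)
with match +1, mismatch −1, gap open −5, gap extend −1; a gap of length L
costs `open + (L−1)·extend`. `N` and IUPAC ambiguity codes match nothing,
including themselves. The DP fill is numba-compiled; the traceback is
deterministic (diagonal over vertical over horizontal), and among
co-optimal end cells the alignment with the smallest start in the first
sequence, then the second, then the fewest gaps is returned. Identity is
matches / aligned columns with gaps counted as columns. These defaults are
conventional for nucleotide repeat annotation; no claim of optimality for
a particular substitution process is made, and the scheme is configurable.

## Genome scanning

Scanning is seed-and-extend: exact 11-mer matches between consensus and
genome (both strands) are grouped by projected element start (tolerance
50 nt); groups with fewer than 3 seeds are discarded — in a megabase-scale
genome isolated 11-mer collisions are expected by chance (≈0.5 per kb of
query) while a genuine copy at ≤10% divergence retains dozens of intact
seeds. Each candidate locus is verified by optimal local alignment of the
consensus against the windowed genome sequence. Same-strand hits
overlapping >50% reciprocally are merged, as are hits ≥90% contained in a
higher-scoring hit; the containment rule exists because a query with two
LTRs generates partial self-hits inside every full-length hit.

## Clustering

Family clustering is single linkage under the classic repeat-library
predicate: two sequences are linked when a local alignment covers ≥75% of
the shorter sequence at ≥75% identity. The partition is independent of
input order. A shared-8-mer prefilter (threshold 8, applied only to pairs
of sequences ≥200 bp) skips alignments between sequences that cannot
plausibly reach the identity threshold: unrelated 600-mers share ≈5.5
distinct 8-mers by chance, while sequences at even 70% identity share
dozens.

## Consensus building and terminus extension

Multiple alignments are center-star: the member with the greatest total
pairwise score is the center, every other member is locally aligned to it,
and pairwise gap structures are merged into common columns. A refinement
pass realigns all members against a scaffold in which the first-pass
majority consensus replaces the center's core; this restores characters
that are lost when the center itself carries a deletion (other members'
insertions otherwise scatter across adjacent columns and fall below the
majority threshold).

The consensus follows the 50% majority rule, made total and deterministic:
a column whose gap frequency reaches 50% is dropped; otherwise the most
frequent base is emitted if it reaches 50% of the non-gap characters
(ties break by the fixed order A<C<G<T) and `N` otherwise.

Because members are whole genomic windows, columns outside the homologous
core are superpositions of unrelated flanks. Each column's *support* (the
fraction of members agreeing with the consensus character) separates the
two regimes cleanly — near 1 inside the element, ≈0.35 outside — so the
consensus used for terminus detection is the longest run whose smoothed
(15-column moving average) support reaches 0.55, padded by 50 columns per
side so genuine terminal bases are never clipped.

Terminus extension iterates, up to 10 rounds: re-scan the genome with the
current consensus; take the 10 best hits that cover ≥60% of it (partial
hits such as solo LTRs all stack onto one LTR of the alignment and would
otherwise push genuine terminal columns over the gap-majority drop rule);
extract them with 500 bp flanks; rebuild the consensus; detect the LTR
pair; and corroborate the element boundaries with TSDs. The loop stops
when the element and LTR lengths are stable to ±2 nt in two consecutive
rounds. The final consensus is trimmed to the element; TSDs, being
target-derived, are excluded. If no termini are ever found the family is
returned unpartitioned with a `no_termini` flag.

### Boundary corroboration by TSDs

LTR-pair detection alone is ± a few nt: flanking consensus columns can
match by chance, and a 5 bp TSD overshot by one base still leaves a 4 bp
exact duplication. Boundaries are therefore refined over a ±8 nt grid: for
each candidate, every member window is re-anchored by locally aligning the
candidate element consensus to it (alignment-trimmed termini are projected
back through the query offsets, so a copy whose edge base mutated still
votes at the right position), and the member's flanks are tested for an
exact 4–6 bp duplication. Candidates are ranked by total duplicated
length, with any single TSD sequence counted at most twice — real TSDs are
target-derived and differ between copies, whereas an element-internal
near-terminal repeat fakes the *same* duplication in every copy — then by
member count, then by the smallest adjustment. The family TSD length is
the mode over supporting members.

## Structural annotation

* **LTR pair**: best local alignment between a prefix and a suffix window
  (default depth `max_ltr + 100`, capped at half the sequence so the
  windows never overlap), requiring ≥80 aligned columns at ≥80% identity,
  then exact outward extension. For a sequence that is exactly one element
  the boundaries are anchored to the sequence ends (snap ≤5 nt, preserving
  the repeat relation). The 80 nt / 80% defaults reflect the observed LTR
  size range and are configurable.
* **TSD**: longest exact duplication of length 4–6 between the left-flank
  suffix and right-flank prefix. Exactness is deliberate: TSD length is
  treated as a clean family diagnostic.
* **PBS**: the first 50 bp of the internal region are searched against
  every library tRNA in two priming modes — complementarity anchored at
  the mature 3' terminus (spliced tRNA plus the post-transcriptional CCA),
  and complementarity covering the anticodon loop (positions 32–40 of the
  spliced tRNA; 3'-truncated priming). A call needs ≥8 paired bases
  beginning and ending in pairs; one internal mismatch is tolerated only
  in duplexes of ≥12 nt (a mismatch inside a shorter duplex is not
  credible complementarity, and with a whole tRNA library to scan it would
  produce frequent chance calls — the null rate over 1000 random internal
  regions is under 5% with these settings). Splice-awareness matters: for
  intron-containing tRNAs the anticodon-loop region is contiguous only in
  the mature tRNA.
* **PPT**: the right-most window of ≥10 nt with ≥80% purines ending
  within 5 nt of the 3' LTR junction, extended leftward while the fraction
  holds. These thresholds are this package's operational definition; the
  literature rarely defines the PPT numerically.
* **Solo LTRs**: an LTR-consensus hit covering ≥90% of the LTR, with no
  internal-region hit within 50 nt, whose projected full-LTR extent (±2 nt
  for alignment drift) is flanked by an exact 4–6 bp TSD.

## Promoter scanning and classification

The tRNA-type scanner looks for box A as the bipartite IUPAC pattern
`TRGCY`, a 2–12 nt linker, then `YGG`, with at most one mismatch across
both parts, followed by an exact `GGTTC` box B starting 20–80 nt after the
box A start; the earliest qualifying pair wins. The 5S-type scanner
requires box A, IE and box C in order with configured spacing (defaults:
IE 2–10 nt after box A, box C 5–15 nt after IE) and at most one mismatch
per box; the default motif strings are substrings of a bundled synthetic
human-like 5S rDNA reference (`data/pol3_5s_motifs.yaml`) at the canonical
internal-control-region positions, and are meant to be replaced with
organism-specific patterns via that config.

Specificity differs sharply between the two architectures: the 5S motifs
(14 + 6 + 11 specified positions) essentially never fire on random
sequence, while the short bipartite tRNA-type pattern fires on ≈14% of
random 300-mers. Classification therefore leans on structure: a family is
`TRIMp3_tRNA` or `TRIMp3_5S` when either LTR consensus scans positive
(if both architectures fire, the higher motif score wins and ties are left
unclassified), `TRIMp2` otherwise. Families of 1000–1300 bp carry a
`long_trim` flag (the TRIM label is conventionally reserved for elements
under ~1 kb, but bona fide families slightly above it exist); beyond
1300 bp the label is withheld.

## Phylogenetics

Pairwise distances are Jukes–Cantor, `d = −(3/4)·ln(1 − 4p/3)`, with `p`
the mismatch proportion over columns where both rows carry an unambiguous
base (pairwise deletion). Saturated pairs (`p ≥ 3/4`) are capped at 5
substitutions/site — promoter-derived alignments are short and can be
deeply diverged, and the correction is undefined there. Trees are built
with BioNJ (variance-weighted neighbor joining): the standard Q criterion
selects each join, branch lengths come from the usual three-point
formulas (negative estimates clamped to zero), and the reduced distances
use the variance-weighted update with λ clamped to [0, 1]; ties break
toward the earliest pair in taxon order. On additive matrices the method
recovers the generating tree exactly; a five-taxon case is additionally
frozen against an independent R implementation. Bootstrap support is the
percentage of column-resampled replicates (seeded, default 100) containing
each internal bipartition of the reference tree.

## Copy counting

A hit counts as a full-length LTR (or internal) copy when its aligned
length is **strictly greater** than 90% of the respective consensus length
and its identity **strictly greater** than 90% — the conventional reading
of "longer than 90%" and "over 90%". LTRs and internal regions are counted
independently, so the LTR count of a family with solo LTRs exceeds twice
its internal count.

## The synthetic benchmark

`simulate.plant_elements` writes copies of generated ancestral elements
into an i.i.d. uniform background (GC configurable), each with its own
substitutions (i.i.d. per site), short 1–3 nt indels at 0.2× the
substitution rate (kept low so that oracle alignments stay unambiguous),
a fresh exact TSD, a random strand, and — for `round(solo_fraction ×
copies)` of them — collapse to a solo LTR retaining the TSD pair.
Placement is non-overlapping with ≥200 bp spacing and ≥700 bp end margins.
Everything derives from one seeded generator: a seed reproduces the genome
byte for byte.

The benchmark scenario (`benchmark.run_round_trip`) plants three
archetypal families in 2 Mb — tRNA-promoter/anticodon-loop/5 bp TSD
("fungal-like"), tRNA-promoter/3'-end/4 bp TSD ("animal-like"), and
5S-promoter/3'-end tRNA-Leu/5 bp TSD ("Ajax-like") — 10 copies each at 2%
divergence with 30% solos, then runs discovery from truncated seeds
(the central 60% of each ancestor, so terminus extension is genuinely
exercised) and scores consensus identity, boundary accuracy, TSD/PBS/class
calls and copy counts against the truth table. The copy-count expectation
applies the strict >90%/>90% rule to each planted copy individually: at 2%
divergence an occasional copy draws a heavy mutation load and legitimately
fails the rule, and the pipeline is expected to agree with that judgement,
not to count the planted copy regardless.

What the benchmark does **not** emulate: real repeat landscapes (nested
insertions, 5' truncations, tandem arrays, segmental duplications, GC
heterogeneity, other repeat families as background), phylogenetic
structure among copies (star phylogeny only), or genome-scale copy numbers
(hundreds to thousands of copies in multi-hundred-Mb assemblies). Passing
it shows the machinery is correct on clean planted signal at modest
divergence; sensitivity on ancient, fragmented families in real genomes is
a separate question that the iterative extension loop only partially
addresses.

## Problem sizes

Default validation sizes — 2 Mb genomes, 10 copies per family, 20 seeds
for the round-trip benchmark, 1000-trial Monte-Carlo nulls, 100 additive
matrices of 4–12 taxa — were chosen so the full suite exercises every
stage end-to-end in a few minutes on a single core while keeping binomial
confidence intervals on the measured rates tight enough to be meaningful.

## Known limitations

* The center-star MSA is O(n²) in members and approximate; it is adequate
  for ≤10 well-conserved copies but is no substitute for a progressive
  aligner on divergent families.
* TSD detection is exact-match by design; lineages with degenerate TSDs
  would need a relaxed comparator.
* The tRNA-type promoter pattern is intrinsically low-information;
  single-sequence calls should be treated as hypotheses, not assignments.
* Anticodon-loop PBS detection assumes the conventional loop position
  (32–40) on the spliced tRNA; non-canonical tRNAs would need per-library
  loop annotations.
* The scanner's k-mer seeding (11-mers, ≥3 per locus) bounds detectable
  divergence at roughly 15%; older copies are invisible to the default
  settings.
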