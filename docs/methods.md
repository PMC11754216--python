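# Methods

This note records how `vdjloci` models each step, which knobs matter, what the
synthetic-data generator does and does not emulate, and the numerical and
design choices made where several defensible options existed.

## Coordinates, alignment and identity

Internally all intervals are 0-based half-open on the forward strand; GFF3
output converts to 1-based inclusive. Pairwise alignment (global,
semi-global "fit", and local) is affine-gap with the convention that a gap of
length *k* costs `gap_open + k·gap_extend`; defaults are match +2,
mismatch −1, gap_open −4, gap_extend −1, chosen as ordinary nucleotide-level
settings and exposed on every alignment call. Percent identity is counted
over columns where **both** rows are non-gap, and `N` never counts as a
match. The denominator choice matters because the 80 % family threshold is
interpreted against it: counting all columns (gaps included) would deflate
identities of length-mismatched pairs and split families; our definition is
the more permissive one and is applied consistently in tests and defaults.

## RSS model

A recombination signal sequence is scored as the sum of per-position log-odds
(bits) of the heptamer and nonamer against a background of 0.25 per base;
`N` contributes 0 bits. The spacer contributes no score, only a length
constraint: 12 or 23 bp ± a tolerance (default ±1, reflecting the well-known
natural variability of spacer lengths; exact 12/23 arrangements remain the
canonical case). The default model concentrates 0.97 of the probability mass
on the consensus base at the first three heptamer positions (`CAC`, essential
for cleavage) and 0.85 elsewhere (`AGTG` and the nonamer `ACAAAAACC`). The
scan threshold defaults to 60 % of the model's maximum score (~17.3 of 28.8
bits): high enough that a 10 kb random sequence yields on the order of one
spurious raw hit, low enough that the functional non-canonical heptamer
variant `CACAGCA` observed in several squamate loci still passes (20.6 bits).
Models are trainable from example (heptamer, spacer, nonamer) triples with a
pseudocount, so a user with curated RSS can replace the consensus model. Only
rank behaviour is contracted — consensus scores highest, known variants score
far above random; no parity with any external RSS-scoring service's numeric
values is claimed.

## Segment calling

Segments are derived from RSS geometry plus coding-signal checks:

* **V**: window immediately 5′ of a 23-RSS heptamer on the same strand,
  length a multiple of 3 in [270, 330] nt (typical TCR V exon sizes),
  beginning with ATG and stop-free; the **longest** qualifying window is
  taken. V exons are modelled as single exons — no leader/L-part1 splitting —
  a documented simplification.
* **D**: window of [8, 25] nt between an upstream 12-RSS and a downstream
  23-RSS facing it (the TCRβ/TCRδ-style architecture that permits V–D–J
  order under the 12/23 rule).
* **J**: window of [30, 70] nt immediately 3′ of a 12-RSS, ending right
  before a splice-donor `GT`, stop-free and containing the F-G-x-G anchor;
  the **shortest** qualifying window (first donor) is taken.
* **C**: never called from RSS; located by fit-aligning known C sequences or
  transcript evidence, as constant regions carry no recombination signals.

Conflicts are resolved greedily by descending combined RSS score with
leftmost tie-break, each heptamer consumed at most once; displaced candidates
are dropped with a logged warning. This is deterministic and simple; nothing
in the biology dictates a particular conflict rule because planted and real
architectures rarely produce genuine conflicts. Naming follows the IMGT
convention of numbering 5′→3′, with V segments named `<locus>V<family>.<member>`.

## Family clustering

Families are defined at ≥80 % pairwise nucleotide identity. Single linkage
(connected components of the ≥threshold graph) is the default because "sharing
≥80 % identity" is most weakly read as chain-connectivity; complete linkage is
available when every within-family pair must satisfy the threshold. Labels
are canonicalized by each family's 5′-most member, making the assignment
invariant to input order. Identity is computed on the untrimmed, coding-strand
nucleotide sequence; no codon-aware alignment.

## Repertoire classification

Transcripts are mapped to germline segments by **local** alignment rather
than fit alignment: exonucleolytic trimming during recombination makes the
germline ends non-homologous to the transcript, and forcing a full-germline
fit would smear the junction boundaries. A cheap shared-12-mer prescreen
shortlists candidate germline segments before alignment; order (and hence the
leftmost-tie rule) is preserved. Assignments require ≥90 % identity and a
minimum germline coverage (V 15 % — truncated transcripts must still be
assigned; J 50 %; C 70 %).

* **5′-completeness** is operationalized as the V alignment covering ≥95 %
  of the germline V (the source criterion is qualitative; 95 % separates
  full-length-with-trimming from genuinely truncated cDNA ends cleanly).
* **Frame** is anchored on the germline V codon frame at the V-alignment
  start; a transcript is in frame iff the C anchor lies a multiple of 3
  downstream. Anchoring on V and C (not J) makes the call robust to exactly
  where the junction boundary is drawn when N nucleotides happen to match
  germline.
* **Stops** are scanned from the anchored V start through the end of the J
  alignment only; stops within C are not evaluated (junction-focused
  definition).
* **D evidence** is the longest exact junction/germline-D substring match
  (≥8 nt), reported only; it never affects productivity.

`productive ⇔ complete ∧ in-frame ∧ no-stop` is asserted on every output.
Percentages are reported to one decimal with half-up rounding.

## Transmembrane and pairing

TM detection is a Kyte–Doolittle sliding window: the 19-residue window of
maximal mean hydropathy is accepted if its mean ≥1.5, then extended outward
(left flank first) while flanking residues stay hydrophobic, to at most 25
residues. Ties between windows are resolved leftmost within a 1e-9 float
tolerance (exact ties are common in designed sequences). This is a
deterministic functional stand-in for neural-network TM predictors, adequate
for single-pass receptor chains; it is not suitable for multi-pass topology.
Chain classes follow the conserved TCR charge asymmetry: both Arg and Lys in
the TM → `RK`; Lys only → `K_only`; neither → `none`. A heterodimer is
predicted compatible exactly when one chain is `RK` and the other `K_only`.
Classification is by presence within the detected TM, not by any absolute
alignment position.

## Phylogenetics

Distances are uncorrected amino-acid p-distances with pairwise deletion
(columns where both rows are non-gap); a Poisson correction `−ln(1−p)` is
available for deeper divergences. Neighbor joining is the classic Saitou–Nei
agglomeration with negative branch lengths clamped to zero and a
deterministic tie-break: among Q-minimal pairs, join the pair whose sorted
representative leaf names (lexicographically smallest leaf under each
cluster) sort first. Bootstrap resamples alignment columns with replacement;
support of an internal bipartition of the full-data tree is the percent of
replicate trees containing it (bipartitions canonicalized to their smaller
side). 1,000 replicates is the conventional default; tests use 20–200 to
keep runtimes short, which is sufficient for the planted two-clade designs
they check. Trees of *real* V-gene sets are topology-fragile — bootstrap
values on deep splits are routinely low — so clade-placement claims from real
data are demonstrations, not test contracts.

## Synteny

Gene matching is by name only (case-insensitive, optional alias table);
sequence-homology matching is out of scope. Flanker distances are measured
boundary-to-boundary (end of the 5′ gene to start of the 3′ gene, never
negative), orientation-normalized so the value is invariant under
reverse-complementing a region's coordinates. A gene's order is called
conserved when the same set of shared genes precedes it in both regions.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

* **Locus**: V families seeded from random ATG-initiated stop-free ORFs
  (300 nt), rejected until pairwise prototype identity ≤ the between-family
  target (default 70 %); members mutated at `L(1−w)/2` positions so pairwise
  within-family identity lands at the target *w* (default 85 %) ± ~3.
  Every V gets a canonical 23-RSS, every D a 12-RSS (V-proximal) and 23-RSS
  (C-proximal), every J a 12-RSS and a splice-donor GT. The first D core is
  the deeply conserved vertebrate `GGGACAGGGGGC`. One C exon encodes a
  transmembrane helix with a single planted Lys (K-only class) by default.
  Inverted V genes are emitted as reverse complements 3′ of C. Intersegment
  gaps are i.i.d. uniform nucleotides of uniform length in [200, 800] bp.
  Defaults mirror a skink-like TCRβ architecture: 16 V in 8 families, one
  inverted V, 3 D, 6 J, 1 C. A `noncanonical_heptamer` option plants
  `CACAGCA` to exercise scanner tolerance.
* **Repertoire**: uniform V/D/J choice under the 12/23 rule, uniform trims
  (V ≤6, D ≤3 per side, J ≤4 nt) and N-addition lengths (≤6 nt); the
  junction length is adjusted mod 3 to force the configured fraction of
  frame-preserving joins, and frame-preserving junctions are resampled until
  stop-free, so `productive-of-complete` equals `target_frame_fraction`
  exactly in expectation. A configured fraction of transcripts is truncated
  within V (10–80 % of the V removed) to model incomplete 5′ ends. Defaults
  reproduce the composition reported for skink TCRβ spleen transcripts:
  52.6 % complete, 80 % productive-of-complete, 38 transcripts.

Three construction guarantees make annotator recovery exact rather than
approximate: a `TAA` guard immediately 5′ of each V ATG blocks any longer ORF
window; the F-G-x-G anchor occupies the last four J codons and nowhere else,
so the shortest-donor rule stops at the planted donor; D cores contain no
stop triplet at any offset, and the all-C fallback for forced-in-frame N
regions is stop-free across every junction boundary (stop codons contain
no C).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: repeat structure and GC heterogeneity of intergenic
DNA, leader exons and introns within V genes, pseudogenes and decayed RSS,
non-uniform trim/N-addition distributions, allelic variation, sequencing
error, and chimeric or partially assembled transcripts. Exact
precision/recall on synthetic loci demonstrates the correctness of the
geometry and bookkeeping, not robustness to assembly artefacts.

## Problem sizes in tests and the acceptance script

Tests annotate 20 locus/seed architectures (2–20 V, 0–3 D, 1–6 J, 0–5
inverted V; ~19 kb each), cluster up to 50 V segments over 10 seeds, and
classify 2,500 simulated transcripts (5 seeds × 500); the acceptance script
uses the same sizes and finishes in about a minute on one CPU. These sizes
were chosen as the smallest that exercise every architecture feature and give
binomial confidence intervals of ±2 % on the repertoire fractions.

## Known limitations

* No pseudogene/functionality classification of germline segments.
* No splice-site modelling beyond the GT donor check; no leader exons.
* Identity values are not guaranteed to match any particular external
  alignment program's guide-tree-dependent identities; the contract is the
  internal definition above.
* Haplotype reconciliation (merging segment sets called on two
  pseudohaplotypes) is not implemented.
* The D-evidence call is conservative: heavily trimmed D cores (<8 nt
  remaining) go undetected by design.
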