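# Methods

## The locus model

`trgkit` models a TRG locus as a forward-strand sequence containing tandem
V-J-(J)-C cassettes. Loci annotated on the minus strand of an assembly are
expected to be reverse-complemented once at load time; all coordinates are
1-based, fully closed, and refer to the working (forward) strand. All genes
of a locus are assumed co-oriented — cassette loci of this family have every
gene in the same transcriptional orientation, and mixed-orientation loci are
out of contract.

Gene anatomy as the annotator understands it:

- **V**: L-PART1 (ATG-initiated leader exon ending at a GT donor), an intron
  ending at an AG acceptor, the V-EXON, and a 3′ 23-RS. The 23-nt spacer is
  the standard configuration for TRGV genes and is the default; it is
  configurable.
- **J**: a 5′ 12-RS, a J-REGION of roughly 40–75 nt whose translation ends
  at (or within a few codons of) the canonical FGXG motif, and a 3′ GT donor.
- **C**: EX1, one to three EX2 copies (EX2A/B/C), EX3 ending at the
  terminator, separated by canonical GT..AG introns.
- **PJ / En**: the germline J promoter upstream of the C-distal J and the
  enhancer-like element ~2 kb downstream of C; both carry at least one STAT
  consensus motif (TTCNNNGAA).

## RS detection and scoring

An RS candidate is heptamer + spacer + nonamer scanned on the forward strand
(the reverse strand is scanned by reverse-complementing and mapping
coordinates back). The score is

```
0.6 * (heptamer matches to CACAGTG)/7
+ 0.4 * (nonamer matches to ACAAAAACC)/9
- 0.05 * |spacer length - nominal (12 or 23)|
```

with spacer deviation up to ±1 tolerated. The first three heptamer bases
(CAC) are crucial for recombination: a site with a broken core keeps its
uncapped `motif_score` but its reported `score` is capped at 0.65, so it can
never pass the default 0.7 reporting threshold. The weights, tolerance and
thresholds are package choices (the biological literature specifies only
that the RS must be "proper" and the CAC core crucial); all are
configurable via `RunConfig`.

Gene *calling* applies a stricter floor: an RS anchors a gene only if its
uncapped motif score reaches `rs_call_score` (default 0.9). Germline RS of
functional loci are near-consensus in the crucial positions, and the high
floor is what keeps annotation precision at 1.0 against random background.
Core-broken but otherwise near-consensus RS still anchor genes — such genes
are classified ORF, matching how a J gene with a mutated cac core is
annotated rather than dropped.

## V/J/C calling rules

**V**: for each called 23-RS, the V-EXON is the longest exon in the
configurable 200–380 nt range that opens at an AG acceptor and ends at the
RS. L-PART1 maximizes leader length over (GT donor, ATG) pairs with intron
length 60–150 nt and leader length 30–63 nt. If no donor exists but an ATG
sits where a modal-length (45 nt) leader would put it, the leader is called
with a non-canonical-donor defect (the classic TRGV6 situation). Candidates
whose exon cannot be read in any natural frame with at most 3 stops are
rejected as non-genes; this cutoff separates true genes (0 stops, or a
handful after a recent frameshift) from random open sequence (about one stop
per 21 codons).

**J**: for each called 12-RS, GT donors 40–75 nt downstream are enumerated;
each candidate J-REGION is translated in its donor-anchored frame and the
candidate whose rightmost FGXG sits closest to the 3′ end wins (full motif
within 3 codons of the end; an F-x-x-G degraded motif within 2 codons is
accepted with a "J-motif" defect, which classifies as ORF). A credible RS
with no donor in the window yields a modal-length (51 nt) J with a splice
defect.

**C**: reference C exons (EX1/EX2/EX3 from a related locus or the
simulator's truth set) are located by iterated semi-global alignment
(edlib): find the best placement, accept it above 60% identity over the full
exon, mask, repeat. Each accepted hit is then *refined* with an affine-gap
alignment (match +1, mismatch −1, gap open −12, extend −3, free end gaps on
the genomic window only). The heavy gap cost matters: paralogous exon copies
differ almost exclusively by substitutions, and unit-cost edit paths
routinely fabricate compensating indel pairs that would corrupt exon
boundaries and frame inference. A gap is kept only when it buys a clear
improvement (more than 3 extra matches) over the gap-free reading — which a
genuine frameshift always does, because everything downstream of a real
indel is misaligned in the gap-free reading. Hits are chained 5′→3′ into
EX1–EX2×k–EX3 genes (k ≤ 3) across GT..AG boundaries; borderline-identity
hits are believed only when flanked by the splice dinucleotides appropriate
to their class.

**Functionality** follows the standard germline rules: P if any coding exon
has an internal stop codon or a frameshift (length inconsistent with frame,
mod 3); otherwise ORF if the RS core is broken, a splice site is
non-canonical, the J motif deviates, or the leader is missing; otherwise F.
A P gene whose coding region is matched at ≥ 95% identity (configurable
within [0.9, 1]) by a cDNA segment that is stop-free in some frame is
rescued to F, with the cDNA segment recorded as the corrected sequence.

## Subgroups

V genes sharing **strictly more than** 75% nucleotide identity over
L-PART1+V-EXON belong to one subgroup. Identity comes from global alignment
(match +1, mismatch −1, first gap residue −5, then −1) with columns under
terminal gaps excluded, so end-length differences do not dominate. Because
the criterion is pairwise, subgroups are the transitive closure (single
linkage) of the thresholded relation; the partition is invariant under input
order and can only refine as the threshold rises.

## Architecture

The dot-plot is seed-and-chain: exact k-mer matches (default k = 12) between
the sequence and itself, chained along equal diagonals with gaps ≤ 50 nt,
runs ≥ 200 nt reported, each with its mirror partner; lowercase (masked)
positions seed nothing; over-represented k-mers are skipped. Four identical
cassettes produce three lines parallel to the main diagonal (offsets L, 2L,
3L). Cassette decomposition cuts the position-sorted gene list after each C
gene and demands the V\*J⁺C grammar; violating blocks become explicit
anomalies. Cassette naming assigns each query the reference cassette label
of its C gene's best `pairwise_identity` neighbor, breaking ties by V-gene
identity, with < 0.6 identity yielding "novel-n" (a phylogeny-based naming
via `neighbor_joining` + `monophyly_test` is available for the strict
orthology argument). PJ is sought within 2 kb upstream of the C-distal J and
En within 4 kb downstream of C ("about 2 kb" is approximate); accepted
elements report the length of their conserved core, the longest aligned
stretch at ≥ 80% identity. Homology-block painting chains exact k-mer
anchors between cassette-sequence pairs, merges them into blocks by
connectivity (same-sequence runs must overlap by ≥ k to merge, because
chance seed extensions can cross a block boundary by a base or two), and
reports uncovered stretches ≥ 100 nt as private blocks.

## Phylogenetics

The progressive aligner is a deliberately simple, fully deterministic
substitute for a production MSA tool (externally produced alignments can be
imported as pre-aligned FASTA): a UPGMA guide order on shared-k-mer
distances with lexicographic tie-breaks, then profile–profile Gotoh
alignment (match +1, mismatch −1, gap open −4, extend −1; expected score
over column base frequencies, gaps ignored in the frequency). p-distances
use pairwise deletion: for each pair, columns holding a gap or any non-ACGT
code in either row are removed, and the per-pair retained-site counts are
reported. Neighbor joining is the Saitou–Nei Q-criterion with ties broken by
the smallest node-index pair and negative branch estimates clamped to zero
with a warning. Bootstrap supports resample columns with replacement and
count, per internal bipartition of the full-data tree, the percentage of
replicates containing it.

RelTime-style dating operates on the tree rooted on the outgroup's edge
(outgroup excluded from all averaging). At each internal node the two
descendant lineages span the same time, so their relative rates are set
proportional to their tip-count-weighted mean depths; rates compose
multiplicatively toward the tips; node ages follow bottom-up as tip-count-
weighted means of child age + branch/rate, floored just above the deepest
child to keep ages strictly decreasing rootward. This is the plain
relative-rate recursion without rate-merging hypothesis tests or confidence
intervals. Absolute ages scale the calibrated node — the MRCA of two named
taxa — to the midpoint of the calibration interval (67.0 Ma for the default
66–68 Ma dromedary–pig split), then clip into the interval. A zero-length
terminal subtree leaves rates undefined and is an error.

## Repertoire analysis

Each cDNA is matched against every germline V, J and C coding sequence by
semi-global (infix) alignment; the best-identity gene per type is assigned
if it reaches 85% identity over the full germline segment (full-segment
alignment pays for truncation, enforcing the 80% coverage floor).
Thresholds are package choices — the original assignments in this domain
were manual. The junction is the cDNA strictly between the V and J matches;
`intra_cassette` records whether V and J share a cassette and
`c_is_j_proximal` whether the assigned C is the first C downstream of the
assigned J. Summaries report V×J usage counts, the intra-cassette fraction
with a normal-approximation 95% CI, the C-proximal fraction, and the
distinct-transcript count after exact-sequence deduplication. Degenerate
primers match both strands under their own code map; a primer's printed
degeneracy definition overrides the IUPAC table when they conflict, because
it describes the synthesized oligo (the GL2L primer shipped here defines Y
as A/G, as printed).

## The synthetic-data generator

The generator emulates what the downstream stages must detect: tandem
cassettes derived from common ancestral blocks, with per-copy divergence, so
pairwise identity between two copies is about (1−d)² for divergence d.
Defaults mirror the pig locus: 4 cassettes, V counts [5,1,1,1], J counts
[2,2,1,1], EX2 copy numbers [1,3,3,3], divergence 0.10. Each V slot draws
from an ancestral "family" (default: slot i of every cassette shares family
i), which defines the planted subgroup partition; at divergence 0.10,
within-family identity ≈ 0.82 > 0.75 and between-family identity ≈ 0.5, so
the planted partition is recoverable. Segment geometry (leader 45 nt,
V-exon 300 nt, intron 100 nt, J 51 nt within the observed 49–60 bp range,
EX1/EX2/EX3 = 330/60/450 nt) follows stated or typical TR gene sizes and is
configurable; intergenic background is i.i.d. uniform ACGT, and repeats are
not simulated (masking is an input property).

Divergence is **truth-preserving**. Substitutions never touch protected
positions (RS heptamer and nonamer, splice dinucleotides, the initiation
codon, the J motif codons, STAT cores, the terminator), and proposals are
vetoed when they would create an in-frame stop in a coding exon, a decoy AG
or GT dinucleotide inside an intron, a decoy ATG or GT in the leader's
upstream neighborhood, a decoy GT in the J donor's neighborhood, or a
consensus RS heptamer anywhere in background sequence. This encodes
purifying selection on the positions that make a gene a gene, and it is
what makes "recall and precision 1.0 with exact exon coordinates" a
well-defined expectation rather than a statistical accident. The same
discipline means the generator's effective substitution rate at constrained
positions is slightly below the nominal divergence — documented, not
corrected for.

Planted defects are applied after divergence, one lesion per request:
`stop_codon` (an in-frame TAA), `frameshift` (a single deletion; in V exons
the deletion point is chosen so the shifted tail stays nearly stop-free, as
a frameshift surviving in a germline gene implies a recent origin; in C the
deletion mimics the classic single-base EX1 loss at position 114),
`frameshift_leader`, `rs_heptamer_core` (CAC→TAC), `j_motif_second_position`
(FGSG→FASG), and `donor_site` (GT→GC). Each kind maps to the functionality
the classification rules imply (P for stops/frameshifts, ORF for the rest).

Rearranged transcripts are spliced V coding + junction + J + proximal C
coding, drawn uniformly over cassettes that retain a functional V, J and C;
with probability `trans_cassette_rate` (default 0.25, i.e. 75%
intra-cassette, the rate reported for deep expression data in this locus
family) the J and its C come from a different cassette. The junction model
is insertion-only (0–`junction_insert_max` uniform random bases, default
5); exonuclease trimming is available via `trim_max` but defaults to 0,
since junction structure in the source cDNAs is described only
qualitatively. Somatic hypermutation is not simulated.

What passing on synthetic data does **not** show: real loci contain
repeats, diverged pseudogene relics, non-uniform base composition and RS
that drift from consensus, all of which the generator idealizes away. The
recovery results certify the pipeline's logic and coordinate arithmetic,
not its robustness to assembly artifacts.

## Problem sizes and numerics

The test and acceptance workloads use 20 simulated loci (~33 kb each) for
the recovery suite, 100 random additive matrices (n ≤ 8) for NJ, 100 random
alignments for the p-distance oracle, and 10,000 transcripts for the
repertoire statistics — sizes at which every check is exact or
statistically unambiguous. Ties are broken lexicographically throughout
(taxon ids, node indices, diagonal preference in DP traceback) so all runs
are reproducible bit-for-bit for a fixed seed. NJ clamps negative branch
estimates to zero; RelTime floors a parent's age an epsilon above its
deepest child; the affine-gap conventions everywhere charge the open cost
to the first gap residue.

## Known limitations

- Mixed-orientation loci and D genes are out of scope (TRG has none).
- The annotator's V grammar assumes a phase-0, single-intron leader; exotic
  leader structures would need the configurable ranges widened.
- RelTime here is the plain recursion: no rate-merge tests, no confidence
  intervals; figure-level quantities that depend on a specific external
  aligner's output (total tree lengths, alignment column counts) are not
  reproduced.
- Cassette naming by nearest-neighbor identity approximates the
  phylogenetic classification; the tree-based route is provided but slower.
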