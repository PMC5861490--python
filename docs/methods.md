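# Methods

This note documents the models and procedures implemented in `vitring`,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
make results deterministic.

## Reference curation

Raw 16S sequences carry RDP-style lineages
(`domain;phylum;class;order;family;genus`) in their FASTA headers, any
rank possibly `"unclassified"`. Curation proceeds in order, and each
stage partitions its input — removed records are written to an audit log
with the stage and reason, never silently dropped.

**Trimming.** The gene boundaries are located by the conserved 8F primer
motif `TTGATCCT` (5′) and the anti-Shine–Dalgarno motif `CACCTCCTTN`
(3′, `N` matching any base). The trimmed sequence runs from six bases
before the first 5′-motif occurrence (clamped at the sequence start when
fewer than six bases precede it) through the end of the first 3′-motif
occurrence downstream. Motif search uses first exact occurrence,
scanning left to right; the occurrence choice is a convention, as
conserved motifs essentially never repeat within one gene. When the
motifs are absent, trimming coordinates can be transferred from the best
local alignment to an already-trimmed guide sequence; records with
neither route are flagged untrimmable.

**Filters.** Length bounds are 1120–1660 bp inclusive — 16S genes
outside this range are nearly always mis-annotated fragments or fusions
with flanking regions. Homopolymer runs of ≥ 10 identical bases
(parameterized as `max_run = 9` to make the boundary explicit) indicate
pyrosequencing artifacts.

**Clustering.** Nearly identical database entries are collapsed by
greedy centroid clustering: records sorted genus-classified-first, then
descending length (ties by id, for determinism), scanned once; each
record joins the *first* cluster whose representative aligns locally at
≥ 94 % identity with ≥ 90 % of both sequences covered, else founds a new
cluster. The sort order ensures representatives are long, classified
sequences. Identity is matches / aligned columns (gap columns included);
coverage is aligned span / sequence length, per sequence. These are
reasonable conventions rather than a bit-for-bit reproduction of any
particular clustering tool.

**Finalization.** Representatives are removed only when flagged chimeric
by *both* a de novo and a reference chimera screen (the flags are
caller-supplied annotations — chimera detection itself is out of scope),
or when their genus is `"unclassified"`. A classified, unflagged
representative is never removed. The two removal classes are assumed
disjoint in reporting: a representative flagged both ways counts as
chimeric.

**Layout subsampling.** For the phylum-level layout, up to 30 records
per phylum are drawn uniformly without replacement (all records when a
phylum has fewer); the hyper-diverse Proteobacteria are sampled per
class instead. Sampling is reproducible under a seed, with group keys
and member ids sorted before drawing so results are byte-identical
across runs.

## Distances, tree and circular layout

**K2P distance.** Over a gap-aware pair of aligned sequences, columns
with a gap or ambiguous base in either sequence are excluded; with P and
Q the transition and transversion fractions among the rest,
d = −½·ln((1 − 2P − Q)·√(1 − 2Q)). Saturated pairs (log argument ≤ 0)
are recorded and replaced by 1.5× the largest finite distance in the
matrix, so downstream steps stay defined while saturation remains
visible in the logs. The multiple alignment itself is an input: the
package does not align (the synthetic generator produces gap-free
alignable sequences, so tests need no aligner).

**Neighbor joining** follows Saitou–Nei agglomeration (delegated to
scikit-bio's implementation), with negative branch-length estimates
clamped to zero. On additive matrices the tree's patristic distances
reproduce the input exactly; the tests verify this to 1e-9 against an
independent path-summing oracle.

**Tree topology scanning** linearizes the tree into a single leaf order.
Rooting at a chosen initial leaf, the farthest leaf is selected first;
thereafter the smallest ancestral clade of the previously selected leaf
that still contains unordered leaves supplies the next selection (again
the farthest from the initial), expanding outward through peripheral
clades until every leaf is ordered. The far-to-near sequence is
reversed and prefixed with the initial leaf. Two conventions are
deliberate: (i) "distance" is the K2P matrix distance by default — the
same quantity used to find the farthest leaf — with patristic tree
distance available via a switch, since either reading is defensible and
both reproduce the six-leaf worked example; (ii) distance ties break by
lexicographic id.

**Circular placement.** Gaps between consecutive leaves are their
pairwise distances; the ring closes with the last-to-first distance
(the closure rule is a package convention). Angles are cumulative gap
fractions of 2π; all-zero gaps fall back to uniform spacing. Taxon
(phylum/class or genus) positions are circular means of member angles
(atan2 of summed unit vectors); a degenerate antipodal mean ties toward
the smallest member angle.

## Identity search

Indexing and searching are separate steps: the reference database
changes rarely, so the postings table (every non-N k-mer of every
reference, k = 16 by default) is serialized to JSON and reloaded per
query batch. A query is searched on both strands; candidate references
are ranked by shared-seed count, and the top candidates (8) are aligned
locally (affine gaps: match +1, mismatch −1, gap open −2, extend −1)
against a window of the reference around the dominant seed diagonal
(±60 bp padding). The single best hit passing identity ≥ 80 % and
alignment length ≥ 100 bp is reported; ties break by higher identity,
then longer alignment, then lexicographic reference id. Alignment length
counts all aligned columns including gaps.

The 100 bp default reflects the profiling workflow for reads ≥ 100 bp; a
50 bp threshold remains available as a parameter for short-read
screening. Seed-and-extend search can miss a true hit only when
mutations destroy every exact k-mer seed — at the 80 % identity floor
this is rare for ≥ 100 bp queries and is the same sensitivity trade
every seeded aligner makes.

The negative screen classifies reads against a decoy index
(eukaryote 18S / mitochondrial rRNA) at the same thresholds; reads
hitting both the positive and the negative database are excluded from
profiling.

## Genus profiling and copy-number normalization

Reads whose top hit reaches ≥ 94 % identity contribute one count to the
genus of their reference; reads below the threshold are reported as
unassigned and excluded from relative abundances. Because genomes carry
1–15+ copies of the 16S gene, raw counts estimate gene abundance, not
organism abundance. Normalization weights each read by 1/c, with c the
copy number of the read's nearest neighbor in a copy-number reference
database (one 16S sequence per genome-sequenced species), found with the
same 80 %/100 bp search. Inference is per read, not per genus, so mixed
assignments within a genus are handled naturally. A read with no
copy-number hit keeps c = 1 — conservative in that nothing is
down-weighted on missing evidence — and is flagged.

The leave-one-out validator searches every copy-number record against
the database minus itself and reports the fold error
max(t,i)/min(t,i) per record plus the fraction within two-fold. Its
accuracy on any real database depends entirely on how phylogenetically
clustered copy numbers are in that database; the tests verify the
mechanism on constructed cases (clade-constant copy numbers give 100 %
within two-fold; a clade-discordant record exceeds it).

## Reconstruction

Reads classified to the same reference form a bin, minus-strand reads
reverse-complemented. The assembler is a deterministic greedy
overlap-consensus procedure: starting from the longest unused read, the
read with the longest admissible suffix–prefix overlap (≥ 40 bp at
≤ 2 % mismatches) is merged onto either end, with per-column
majority-vote consensus (ties to the alphabetically first base); when no
read overlaps, the contig is closed and a new seed starts. An exact
24-base junction seed short-circuits the overlap scan; the exhaustive
length scan remains as a fallback for error-bearing junctions. Mean
coverage is total read bases placed divided by contig length. The
defaults suit low-error short reads at the coverages where
reconstruction is attempted at all; an adapter accepts externally
assembled contigs so the downstream filters and species calls can be
used with any assembler.

Contigs ≥ 800 bp with mean coverage ≥ 10× are retained and aligned
locally against type-strain 16S sequences; a species name is assigned at
≥ 97 % identity, with exact ties reported as all tied names joined in
sorted order. Local alignment is used deliberately: contigs may carry
ITS or intergenic flanks (they are preserved, not trimmed), which a
global alignment would penalize as terminal gaps.

## Sample comparison

Profiles restricted to confident (≥ 94 %) assignments are compared
pairwise at the reference-cluster or genus level with Jaccard similarity
(supports only), Pearson correlation (abundances on the label union),
and the Yue–Clayton theta θ = Σpq / (Σp² + Σq² − Σpq), which is 1 iff
the profiles are identical and 0 for disjoint supports. Undefined cases
— both profiles empty, or zero variance for the correlation — are
reported as NA and flagged, never coerced to 0.

## Diagrams

Each reference cluster with assigned reads is a dot at its layout angle;
dot *area* (not diameter) is proportional to relative read abundance,
clamped to a visible range (20–2000 px²). The radial position encodes
the cluster's mean top-hit identity in five discrete bands (100, ≥ 97,
≥ 94, ≥ 90, ≥ 80 %) — a reconstruction, since a continuous radial scale
carries no extra information at these thresholds. Clusters absent from
the layout go to a reserved "unplaced" sector with a warning. Rendering
is pure: one spec always produces byte-identical SVG and JSON.

## Synthetic data

The generator emulates the study conditions of short-read 16S
profiling: ~1.5 kb gene-length references carrying the two trimming
anchors at fixed coordinates (anchor columns are frozen during
evolution), species related by a random-join tree with exponential
branch lengths, sequences evolved forward under the exact K2P transition
probabilities (default rates give a 2:1 transition:transversion ratio
and total rate 1, so branch lengths are expected substitutions per
site), 150 bp reads with uniform start positions on either strand, and
a substitution-only error model. Mock communities draw species read
counts with probability proportional to molarity × copy number, the
quantity a shotgun library actually samples; copy numbers default to
1..10 and molarities are log-uniform over one decade. Mock species
trees use a branch-length floor of one third of the target divergence so
no two species straddle the 94 % genus threshold and genus truth stays
unambiguous.

What it does not emulate: indels and platform-specific error motifs,
PCR chimeras, length variation among real 16S genes, intragenomic 16S
polymorphism, and conserved-vs-variable regional rate structure. Tests
passing on this generator therefore demonstrate the correctness of the
algorithms under their stated models, not field performance on real
libraries.

## Problem sizes

The test suite and the acceptance script run on deliberately small
instances chosen to exercise every code path with comfortable margins:
mock communities of 3–10 species, read sets of 150–2000 (50,000 only
for the pure sampling check), references of 300–1500 bp, trees of up to
12 leaves, and 200 random search instances against the exhaustive
dynamic-programming oracle. The reconstruction check tiles one ~1500 bp
gene at ~15× with 150 error-free reads.

## Known limitations

- The assembler is greedy and reference-binned; it is not a general
  metagenomic assembler and will fragment bins whose coverage has gaps.
- Seed-and-extend search trades sensitivity below ~85 % identity for
  speed; exhaustive alignment is available via `align_pair` where
  completeness matters.
- Copy-number inference assumes the nearest database neighbor shares
  the query's copy number; taxa with atypical copy numbers relative to
  their clade are mis-inferred by construction.
- The layout consumes a precomputed multiple alignment; alignment
  quality directly affects distances and hence the circular order.
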