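# Methods

## The linearized-pangenome model

`panpav` represents a pangenome as a set of *panchromosomes*, each a single
linear axis tiled by ordered, non-overlapping *pangenomic blocks* (genes or
sequence segments, typically at 1–10 kb resolution). Coordinates are 0-based
and half-open, following BED. The central object is the PAV matrix: for every
(block, genome) pair a non-negative integer copy count, 0 meaning absent.
Copy counts rather than booleans are stored because a genome's path through a
variation graph can traverse a segment several times; every analysis that
needs presence binarizes at count ≥ 1. A matrix is valid only if every block
is present in at least one genome — a block absent everywhere has no business
on the pan-reference — and blocks on input need not tile the axis
contiguously (gaps are allowed, overlaps are not);
`recompute_coordinates` produces the canonical contiguous tiling from block
lengths when one is wanted, e.g. after graph linearization.

The model assumes the pangenome is *already built and linearized*: block
calling, ordering and homology resolution happen upstream. Repeated blocks
are handled descriptively, not resolved: each block may list
`(panchromosome, start)` positions of similar occurrences, surfaced as a
repeat track and a `repetition_profile`.

## Core/variable classification

A block with presence count *p* among *N* genomes is **core** when
*p / N ≥ t* and **variable** (dispensable) otherwise. The comparison is
inclusive so that *t* = 1.0 means exactly "present in all genomes" — the
strict-core definition — and the classification is monotone in *t*. The
default *t* = 0.95 is the common soft-core convention; every entry point
takes an explicit threshold. Thresholds are expressed as fractions in (0, 1],
never percentages.

## Hollow areas

A *hollow area* is a maximal run of consecutive blocks on one panchromosome
whose **intersection** of per-block absent-genome sets has size ≥ *g*, with
at least *L* blocks. Intersection semantics — the *same* genomes absent
across the whole run, not merely ≥ *g* absentees per block — make the result
unique and testable: extending a run can only shrink the intersection, so a
run is maximal exactly when one-block extensions on either side drop the
intersection below *g*, and overlapping maximal runs with different absent
sets can coexist (all are reported). The threshold is on block count *L*
(not bp span); the bp span is reported per area for the user.

The finder slides a window per panchromosome: per-genome absence counters
over the window give the intersection size in O(genomes) per step, and the
right end never moves backwards, so the scan is O(blocks × genomes). An
interval is emitted when it is right-maximal (the window cannot grow) and
left-maximal (the previous start's maximal window ended earlier). The test
suite checks this against a brute-force enumeration of all O(n²) intervals.

## Genome sorting

All three orderings are deterministic, tie-breaking by matrix order, and
return true permutations:

- **tree**: genomes in the left-to-right leaf order of a Newick tree
  (dendropy); leaves not in the matrix are ignored, matrix genomes missing
  from the tree are appended in matrix order.
- **region pattern**: ascending Hamming distance between binarized presence
  vectors over a block range and a pivot genome's vector; the pivot is first
  with distance 0. A pivot-based distance is the simplest order consistent
  with sorting by "pattern in a region"; hierarchical clustering is a
  non-goal.
- **gene list**: per genome, the number of listed genes whose overlapping
  blocks (card span vs block span, half-open overlap) are all present;
  descending.

## GFA linearization

GFA1 `S` lines give segment lengths (sequence length or `LN:i` tag); `P`
lines define genomes' paths; `L` lines carry no ordering information here and
are ignored. Linearization uses one path as the **backbone**: its segments
keep path order, and each off-backbone segment is inserted immediately after
its *anchor*, the backbone segment most recently preceding it in a path
containing it — the earliest such path in file order decides, segments with
no backbone predecessor go before the first backbone segment, and several
segments sharing an anchor keep their within-path order. This anchor rule is
one deterministic choice among many defensible linear orders and is isolated
in `panpav.gfa` so alternatives can be swapped in. Cell values are traversal
counts; orientation is recorded but ignored for presence (a reverse
traversal still marks presence). Path names `genome#chrom` group paths into
genomes with one panchromosome per chromosome (labelled by the backbone
path's name, backbone selectable by genome name); plain path names mean one
genome per path on a single panchromosome `pan_1`. Conservation laws — per
genome, Σ counts = path length in segments and Σ(count × segment length) =
path bp total — are enforced by tests. Cyclic graphs are only supported
through the traversal-count semantics; W-lines/GFA2 and order optimization
are out of scope.

## File formats

The PAV matrix file is tab-separated with a mandatory header
`#Chromosome Start Stop BlockID SimilarBlocks Function` followed by one
column per genome (integer copy counts). `SimilarBlocks` is `.` or
semicolon-joined `panchromosome:start` tokens; `Function` is free text (`.`
when empty). Canonical output sorts blocks by (panchromosome, start) and
ends lines with `\n`; readers accept `\r\n`. Read∘write and write∘read are
identities on canonical files and matrices respectively (property-tested).
GFF3 is converted between its native 1-based inclusive coordinates and the
internal 0-based half-open convention; `seqid` must be a panchromosome, and
gene → mRNA → exon `Parent` chains are grouped into annotation *cards*
(children with a missing parent become orphan cards with a warning). The
`validate` entry point returns a report of coded ERROR/WARNING issues with
line numbers and is ERROR-free exactly when the reader succeeds. Compressed
streams and GFF3 FASTA sections are not supported.

## Rendering

Rendering is a pure function of (matrix, cards, config) to SVG 1.1: builds a
primitive list, serializes with fixed float formatting, and therefore yields
byte-identical output for identical inputs. Tracks: an overview strip of the
whole panchromosome (each horizontal bin shaded by the mean presence
fraction of blocks overlapping it — the shading statistic is a package
choice; in-view strips cap at 512 bins so wide views stay small); the gene
beeswarm (marks at true x positions, greedily assigned to the lowest
non-overlapping lane, processed left to right with ties by id — the classic
swarm-plot guarantee that no two marks in a lane overlap); a coordinate
axis; the core/variable track; a repeat track with bar height proportional
to repeat count; then one genome row per matrix row, one rectangle per
visible block. Present cells take their block's core/variable colour, absent
cells light gray. Block width in px is bp width × `px_per_bp`, so zooming
rescales x linearly and changes nothing else. Cell rectangles carry
`data-genome`/`data-block` attributes and swarm marks carry `<title>` text,
replacing the hover interactions of a live browser with inspectable static
metadata. PNG export replays the same primitives through matplotlib.

## Synthetic fixtures

`FixtureSpec`/`generate_matrix` emulate a block-level eukaryotic pangenome:
a chosen fraction of blocks forced present in all genomes (core), all other
cells present with probability 0.9, block lengths uniform in 1–10 kb, and
optional planted structure. Background presence 0.9 makes random joint
absences of ≥ 5 consecutive blocks vanishingly rare, so planted hollows are
recovered *exactly*: inside a planted hollow the listed genomes are forced
absent and all others present, and the listed genomes are forced present on
the flanking blocks, making the planted interval the unique maximal one.
Planted repeat groups cross-list members' positions. Each artifact kind
(PAV, GFF3, Newick, GFA) derives its own stream from (seed, kind), so
generators never perturb one another. The generator does **not** model
phylogenetically correlated gain/loss, rearrangement or sequence content —
passing tests demonstrate algorithmic correctness on matrices with realistic
shape and sparsity, not biological realism of the variation process.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` use: 200 random matrices (≤ 8
genomes × ≤ 40 blocks) for oracle equivalence of the hollow finder; 50
seeded specs for planted-structure recovery; 100 matrices for round trips;
100 random graphs for linearization conservation; exhaustive
(presence, N ≤ 30) pairs over a 50-point threshold grid for the
classification laws; and one 300-genome × 50,000-block matrix (the
hundreds-of-genomes scale the tool targets) as a smoke test — about ten
seconds on one CPU. All randomness flows from explicit integer seeds; there
are no tolerances to tune, as every checked property is exact (set equality,
integer conservation, byte identity).

## Known limitations

- The PAV dialect is this package's own: column names and the
  `SimilarBlocks` encoding are fixed here, and genome cells are copy counts
  (an alternative reading — genome-local positions — is not supported).
- Hollow detection thresholds on block count, not bp span.
- The anchor rule gives *a* consistent linearization, not an optimal one
  (no feedback-edge minimization).
- Rendering is static; no interactivity, and no attempt to replicate any
  particular browser's pixel layout.
- No statistical enrichment testing of hollow areas, no clustering-based
  genome ordering, no tree inference, no sequence storage.
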