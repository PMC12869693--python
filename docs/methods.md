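# Methods

## Text model and conventions

The index is built over the *doubled* text: every haplotype walk is spelled
forward and immediately followed by its reverse complement, so the
reverse-complement partner of sequence `sid` is always `sid ^ 1`.  Each
sequence ends with its own end-marker; markers are ordered by sequence id
for suffix sorting and collapse to a single `$` symbol in the BWT.  The
alphabet order is fixed to `$ < A < C < G < N < T`.

Graph positions are `(v, o, b)` triples with the offset `o` counted **along
the traversal direction of the strand**: a walk step `(v, 1)` emits
positions `(v, 0, 1), (v, 1, 1), …` for the bases of the reverse strand in
the order they are spelled.  Node id 0 is reserved; the three reserved tags
are GAP `(0,0,0)` (unassigned rows during construction), END `(0,1,0)`
(end-marker rows, which have no graph base; keeping them tagged makes the
array total), and the B+ tree sentinel `(0,2,0)`.  Queries filter reserved
tags out.

Uniqueness of k-mers is decided over substrings *realized by the indexed
walks* (forward plus reverse complement), not over all graph walks: a k-mer
that only exists on an unrealized path never reaches the BWT, so it cannot
affect anchoring correctness.  K-mers containing `N` are never anchors;
`N` matches literally in `find` but never matches in MEM queries.

## Index internals

Suffix sorting uses Manber–Myers prefix doubling over numpy integer arrays
(sentinels mapped to distinct codes below `A`).  The stored index is the
run-length BWT with per-run cumulative symbol counts (rank by binary search
over run starts), the count array `C`, and locate machinery in the r-index
style:

* SA samples at the first and last row of every run;
* explicit SA samples for every row whose BWT character is `$`.  In a
  multi-string text, LF does not preserve suffix-array adjacency across
  end-marker rows, so these rows both get their own toeholds and contribute
  extra breakpoints to φ;
* a predecessor table for φ (`SA[i] → SA[i-1]`): keys are the SA values at
  run starts plus the `$`-adjacent rows, values the SA of the preceding
  row; between breakpoints φ is linear.  `locate_all` takes one toehold at
  the interval end (`sa_at`, an LF walk to the nearest sampled row) and
  walks upward with φ, touching O(interval + runs) work instead of per-row
  LF chases to end-markers.

Bidirectional (FMD) extension keeps a pattern interval and the interval of
its reverse complement synchronized with the standard cumulative-width rule
over the 6-symbol alphabet; forward extension is backward extension of the
complement with the two components swapped.

## RLB+ tree

The mutable tag store is a B+ tree keyed by run start with implicit lengths;
gaps are materialized as GAP runs so "is this row assigned?" is a plain
lookup and the run sequence always partitions `[0, N)`.  `insert_run`
applies forward/backward/bidirectional merging with equal-tag absorption
(stages may legitimately re-derive a run they already inserted); a
differently tagged overlap raises, because the construction stages can never
produce one — silently resolving it would hide bugs.  Bidirectional merges
can underflow a leaf; rebalancing borrows from a sibling first and merges
second, recursing up the tree.  The default degree is 64 (tests mostly use
4–16 to force deep trees); higher degrees trade pointer overhead against
wider node scans.

## Construction pipeline

Stage 2 processes a breadth-first worklist seeded with the anchor intervals.
At a node start with several predecessors, predecessor positions are grouped
by their final base and only bases contributed by exactly one predecessor are
followed; extended items re-enter the worklist, so branches are themselves
recursively extended.  Work is deduplicated by interval start: a second item
with the same start necessarily carries the same tag (both tags are the
start position of that row's suffix), so re-processing it cannot add rows.
`max_rounds` (default 256) caps pathological unary chains.  Stage 3 is
correct on its own; stages 1–2 exist to keep the tree's run count low while
the array is still mutable.  A disagreement between a stage-3 traversal tag
and an existing tag raises immediately.

Per-component builds keep original node ids, so component tags are valid
global tags.  The merge computes the sequence number of every global BWT row
(one LF walk per sequence, O(N) total) and consumes each component's array
through a cursor; relative suffix order within a component is identical in
the component and global BWTs, which is what makes cursor interleaving
exact.  Cursor under- or over-consumption raises.

## Query structures

The frozen tag array stores run starts in a sorted integer vector (the
sparse-bitvector contract: space ∝ runs, rank by binary search) and one
`(v,o,b)` triple per run.  `distinct_tags` does two ranks, slices the
overlapping runs, and sort-dedups them — cost is measured and asserted to be
output-sensitive, never proportional to interval width.  Output order is
lexicographic by `(v, o, b)`.

The sampled tag array keeps exactly the runs with `o = 0` on either strand
(the strand question is not forced by anything upstream; sampling both keeps
translation strand-symmetric, and callers can collapse).  The value index is
a hash from tag to sampled-run ids — space proportional to sampled runs.
Translation reports node-start resolution only: an interval strictly inside
a node yields nothing, and sub-node offsets are left to the caller's
arithmetic.  The query sequence's own hits are reported (flagged) as a
built-in consistency check; the CLI by default mirrors hits on
reverse-complement sequences onto forward coordinates.

## MEM finding

For each query start the longest match is grown by forward bi-extension;
candidate `[i, e)` is emitted when it is long enough and `ends[i-1] < e`
(left-maximality).  This restarts per position and is quadratic in the
worst case, which is deliberate: the output contract (exact MEM set), not
the traversal strategy, is the normative part, and every reported MEM is
re-validated in tests by interval search plus failed one-base extensions.

## Serialization

The index container is a single JSON file with a magic string and version
number, holding the run-length BWT, samples, φ table, tag array, sequence
and node-name tables.  Integer-only payloads make round trips bit-exact;
version mismatch refuses to load.  Varint/bit-packed encodings would shrink
the file but change nothing observable at the scales this package targets.

## Synthetic data

The generator emulates a bubble-rich pangenome: a random backbone chopped
into nodes of 3–8 bp, variant sites (SNP-bubble / deletion / insertion) at a
per-node rate (default 0.05–0.08 across entry points), haplotypes choosing
alleles with a fair coin, haplotype 0 pinned to the reference path, unused
alternate nodes pruned, and optionally several weakly connected components
as chromosome stand-ins.  It is deterministic per seed down to GFA bytes.
What it does **not** model: long tandem repeats, structural rearrangements,
inversions inside walks (reverse-orientation steps are exercised through the
reverse-complement sequences and hand-written fixtures instead), biased base
composition, and realistic human variant spectra.  Passing the oracle suites
therefore demonstrates algorithmic correctness of the index machinery on
bubble-structured graphs, not calibrated performance on real pangenomes.

Problem sizes in the test and acceptance runs (hundreds of texts ≤ 2 kbp;
50 pangenomes of ≤ ~16 nodes × 8 haplotypes; 10,000 tree operations on
N = 5,000; exhaustive translation on ≤ 6-haplotype graphs) were chosen so
each suite completes in seconds while still exercising splits, underflows,
multi-predecessor extension and multi-component merging; all comparisons at
these sizes are exact, not statistical.

## Known limitations

* Construction is in-memory and single-threaded; no external-memory BWT.
* The k-mer anchor default (k = 31) follows common short-seed practice; the
  choice trades anchor density (small k: fewer unique k-mers in repetitive
  regions) against stage-1 interval width and is freely configurable.
* Translation resolution is node starts; single-target fast paths (anchor
  nodes on chain backbones) are out of scope.
* GFA support covers S/L/P/W with 0M/`*` overlaps; no GBZ, no overlap
  trimming.
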