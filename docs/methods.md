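# Methods

## Model

`hybridec` corrects long reads under the assumption that a deep,
substitution-dominated short-read library from the same sample exists, so
that every correct genomic k-mer is observed repeatedly in the short reads
while erroneous k-mers are rare. The de Bruijn graph over *solid* k-mers
is then a proxy for the genome: any path spells a sequence assemblable
from the short reads, and the best correction of a weak read region is the
path sequence closest to it in edit distance.

Key modelling choices:

- **Canonical k-mers, odd k.** A node stands for a k-mer and its reverse
  complement; counts are looked up on the lexicographically smaller form,
  while traversal stays in the orientation of the query. Odd k guarantees
  no k-mer is its own reverse complement. A consequence worth knowing:
  the graph contains "strand shadow" adjacencies — junctions wherever the
  forward and reverse strands share a (k−1)-mer. At k=19 these are
  vanishingly rare; at toy scales (k=5) they dominate branching.
- **Solidity.** count ≥ s, plus (by default) at least one left and one
  right extension passing the count threshold. The arc requirement is kept
  as a behavioural feature even though this implementation counts k-mers
  exactly in a hash map, where it is no longer needed to suppress
  false-positive membership; it still demotes isolated k-mers. It can be
  disabled (`require_arcs=False`, CLI `--no-require-arcs`).
- **k-mers containing N** are never counted and always weak (conservative;
  the graph should only contain confirmed sequence).

## Search procedures

**Bridging (two anchors).** DFS from the source k-mer, one base per step,
carrying per stack frame one DP row of the unit-cost edit-distance matrix
against the region (region = read substring from the source k-mer's first
base through the target k-mer's last base, anchors included — this
convention fixes the DP endpoints). Row updates are vectorised (the
in-row insertion dependency is resolved with a running-minimum pass).
Pruning is exact, not heuristic: row minima never decrease along a path,
so a branch whose row minimum exceeds E = ceil(max_error_rate × |region|)
cannot recover, and any path longer than |region| + E must also exceed E.
A branch terminates on reaching the target (first arrival; paths passing
*through* the target value are cut there). Ties between equal-distance
paths go to the earliest discovery in A<C<G<T child order, making results
deterministic.

**Branching limit.** Counted as the number of times the DFS takes a
non-first alternative at any node; when it exceeds `branching_limit` the
whole region search returns ABORTED and is treated as failed. This bounds
work deterministically. The default (200) is calibrated for k=19 graphs,
which are near-linear on non-repetitive sequence.

**Extension (one anchor).** Same DFS machinery against the head/tail
segment; with no target, a branch is dropped once its row minimum exceeds
`max_error_rate × (bases consumed)` — a linear drop-off equivalent, under
±1 alignment scoring, to the score falling below L·(1−2e). Among all
stopped paths the longest (then lowest-distance) is kept and trimmed back
by `best_prefix_alignment`: full DP over all (path prefix, segment prefix)
pairs with match +1, mismatch −1, gap −1, ties toward longer prefixes.
Heads are corrected by reverse-complementing anchor and segment and
searching as a tail.

## Path graph and splicing

Nodes are solid k-mer *occurrence positions* (not k-mer values — repeats
make value nodes ambiguous). Weight-0 arcs join consecutive positions
inside a run so the first-to-last shortest-path contract needs no special
cases. Source/target pairs are enumerated per source over the next
`target_count` solid positions, skipping pairs in one run (assumed
correct), overlapping anchors (q − p < k: likely tandem repeat or falsely
solid k-mer), and pairs spanning more than `max_region_span` bases (DP too
large, success unlikely).

Every boundary between consecutive runs that no found bridge crosses gets
a dummy arc from the last position of the left run to the first of the
right run, weighted by the spanned region length, carrying the original
bases. This is slightly broader than adding a dummy arc only after failed
searches: it also covers boundaries where every pair was skipped, and it
is what guarantees the graph invariant (a first-to-last path always
exists). When one-sided flank extensions into an unbridged region succeed,
the dummy replacement carries the partially corrected bases and its weight
drops by the number of corrected bases (floored at 1); an extension is
only used if it leaves the opposite anchor intact, so every replacement
still starts with the source k-mer and ends with the target k-mer — the
property splicing relies on when it drops the k shared junction bases
between consecutive arcs.

The shortest path is computed by relaxation in position order (the graph
is a DAG; this is Dijkstra without the heap), minimising total weight,
then arc count, then the lexicographic node sequence — byte-identical
output for identical input.

Per read: head and tail are corrected first (in both passes), the
partition recomputed, inner regions corrected via the path graph, and the
whole procedure repeated on the reverse complement. A read without a
single solid k-mer cannot be anchored and is passed through lower-case
with a skipped flag. Final case encoding reflects the per-base solidity of
the corrected sequence.

## Synthetic data

The generator's defaults are the package's study conditions: 50 kb i.i.d.
random genome at 50% GC; 75 bp short reads at 50× with 0.5% substitutions,
uniform placement, both strands; long reads uniform in 2–8 kb at 2×
coverage with a 15% per-base error rate split 55% insertion / 30% deletion
/ 15% substitution (the insertion-skewed profile of SMRT sequencing; the
exact split is our choice, exposed in `SimConfig`). Long-read coverage
only sets how many reads are corrected — correction is per-read — and 2×
gives stable position-level totals at desk scale. Every long read records
its exact edit list, so evaluation needs no mapping.

What the simulator does **not** emulate: repeats and biased composition of
real genomes (a random 50 kb genome is nearly repeat-free at k=19, so the
path search rarely faces the hard ambiguous cases), context-dependent or
clustered errors, chimeras/adapters, quality values, and coverage biases.
Passing tests therefore demonstrate correctness of the machinery and
behaviour under the stated error model, not performance on repeat-rich
real data, where Gain is expected to be lower (unresolvable regions are
kept, not corrected).

## Evaluation conventions

The three-way correspondence (original read, corrected read, truth region)
is anchored on truth coordinates. The original↔truth correspondence comes
from the simulator's edit list (exact); the corrected↔truth correspondence
from a deterministic global alignment (edlib's traceback). With many
indels any alignment-based classification is convention-dependent; fixing
the tool (and special-casing corrected == original to share one
correspondence) makes the numbers reproducible. Inserted bases between
truth positions are paired across the two reads: shared insertion columns
are FN, original-only TP, corrected-only FP. A useful invariant: TP + FN
always equals the original read's true error count.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `k` | 19 (odd) | k-mer length; graph order. Larger k: fewer repeat ambiguities, fewer anchors in noisy reads. |
| `solid_threshold` (s) | 3 | min short-read count for a solid k-mer; filters sequencing errors at ≥40× coverage. |
| `require_arcs` | true | solid k-mers must also have ≥1 in- and out-arc. |
| `max_error_rate` | 0.4 | error budget of a correction relative to region length (dimensionless). |
| `branching_limit` | 200 | DFS non-first alternatives before a region search aborts. |
| `target_count` (t) | 5 | targets tried per source around a weak region. |
| `max_region_span` | 500 bases | longest source-to-target span searched (our choice; unstated upstream). |

## Numerical and degenerate-input notes

- DP rows are int32 NumPy arrays; distances are exact integers, no
  floating point enters the search.
- Reads shorter than k, or with no solid k-mer, are skipped (lower-case
  passthrough). Empty read files are valid. All-weak corrected reads trim
  to an empty record (kept, with a warning).
- `sensitivity`/`gain` raise on TP+FN = 0 (no errors to find) rather than
  returning a silent 0/0.
- Determinism: fixed seeds drive all simulation streams (separate
  SeedSequence spawns for genome / short reads / long reads); the searches
  and tie-breaks are fully ordered, so identical inputs give byte-identical
  outputs.

## Problem sizes used by the shipped checks

Unit and property tests run on 2 kb fixture genomes with k ∈ {3,5,7,9,11}
oracle-checkable instances; the end-to-end checks use the 50 kb default
conditions above (about a minute of CPU), and the exhaustive search
oracles check ≥100 instances each with ≤200 candidate paths. These sizes
are the package's chosen desk-scale study conditions.

## Known limitations

- Single-threaded by design (reference behaviour; output must not depend
  on scheduling).
- Exact hash-map k-mer counting holds the index in memory (~tens of bytes
  per distinct k-mer); fine for bacterial-scale data, not for mammalian
  short-read sets.
- The one-sided-correction weight (region length minus corrected bases) is
  a heuristic; alternatives would reweight dummy arcs relative to bridges.
- Head/tail extension in repeat regions can legitimately prefer a longer
  path through a cycle before trimming; at k=19 this is rare, at small k
  it is the expected behaviour of length-maximising extension.
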