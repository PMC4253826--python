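"""Per-read correction: pair selection, path graph, shortest path, splicing.

For one pass over a read, every inner weak region is attacked from several
(source, target) anchor pairs; each successful bridge becomes a weighted
arc of the *path graph*, whose nodes are the solid k-mer occurrence
positions of the read.  Dummy arcs (weight = region length, original bases
kept, possibly improved by one-sided extensions) guarantee the first and
last solid positions stay connected, so a shortest path always exists and
selects which corrections are applied.  Two passes are run, the second on
the reverse complement, because corrections create new anchors and repeat
structure can make the search direction matter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from .dbg import KmerIndex, reverse_complement
from .partition import ReadPartition, partition_read, solid_positions
from .pathsearch import (
    Direction,
    SearchParams,
    SearchStatus,
    bridge_search,
    extension_search,
)

logger = logging.getLogger(__name__)

SKIP_SAME_RUN = "SKIP_SAME_RUN"
SKIP_OVERLAP = "SKIP_OVERLAP"
SKIP_TOO_FAR = "SKIP_TOO_FAR"
SEARCH = "SEARCH"


@dataclass(frozen=True)
class PathGraphArc:
    """Arc of the path graph between two solid k-mer occurrence positions.

    ``replacement`` spans the source k-mer's first base through the target
    k-mer's last base; for dummy arcs it is the original (possibly
    one-side-corrected) read substring.
    """

    src_pos: int
    dst_pos: int
    weight: int
    replacement: str
    dummy: bool = False

    def __post_init__(self) -> None:
        if self.src_pos >= self.dst_pos:
            raise ValueError("arc requires src_pos < dst_pos")
        if self.weight < 0:
            raise ValueError("arc weight must be >= 0")


@dataclass
class PathGraph:
    positions: List[int]
    arcs: List[PathGraphArc] = field(default_factory=list)


@dataclass
class CorrectedRead:
    """Corrected sequence with case encoding: upper = solid, lower = weak."""

    name: str
    seq: str
    skipped: bool = False


def select_pairs(partition: ReadPartition,
                 params: SearchParams) -> List[Tuple[int, int, str]]:
    """Enumerate (source, target) anchor pairs with their action.

    Each solid position is a source; its next ``target_count`` solid
    positions are candidate targets.  Pairs within one run are assumed
    correct; overlapping anchors (q - p < k, across runs) suggest a tandem
    repeat or a falsely solid k-mer; pairs spanning more than
    ``max_region_span`` bases would need an oversized DP matrix.  All three
    cases are skipped; the rest are searched.
    """
    k = partition.k
    positions: List[int] = []
    run_of: Dict[int, int] = {}
    for ri, run in enumerate(partition.runs):
        for p in range(run.start, run.end):
            positions.append(p)
            run_of[p] = ri
    out: List[Tuple[int, int, str]] = []
    for i, p in enumerate(positions):
        for q in positions[i + 1 : i + 1 + params.target_count]:
            if run_of[p] == run_of[q]:
                action = SKIP_SAME_RUN
            elif q - p < k:
                action = SKIP_OVERLAP
            elif q + k - p > params.max_region_span:
                action = SKIP_TOO_FAR
            else:
                action = SEARCH
            out.append((p, q, action))
    return out


def _one_sided_fallback(read: str, p: int, q: int, index: KmerIndex,
                        params: SearchParams) -> Tuple[str, int]:
    """Partial correction of an unbridged region via flank extensions.

    Returns (replacement, corrected-base gain).  The replacement always
    begins with the source k-mer and ends with the target k-mer.
    """
    k = index.spec.k
    region = read[p : q + k]
    span = params.max_region_span
    left = extension_search(read[p : p + k], region[:span], Direction.TAIL,
                            index, params)
    right = extension_search(read[q : q + k], region[-span:], Direction.HEAD,
                             index, params)
    # an extension may not swallow the opposite anchor: the replacement
    # must keep starting with the source k-mer and ending with the target
    l_ok = (left.status is SearchStatus.FOUND
            and left.segment_consumed <= len(region) - k)
    r_ok = (right.status is SearchStatus.FOUND
            and right.segment_consumed <= len(region) - k)
    lu = left.segment_consumed if l_ok else 0
    ru = right.segment_consumed if r_ok else 0
    if l_ok and r_ok and lu + ru <= len(region):
        repl = left.trimmed_seq + region[lu : len(region) - ru] + right.trimmed_seq
        gain = max(0, lu - k) + max(0, ru - k)
    elif l_ok:
        repl = left.trimmed_seq + region[lu:]
        gain = max(0, lu - k)
    elif r_ok:
        repl = region[: len(region) - ru] + right.trimmed_seq
        gain = max(0, ru - k)
    else:
        return region, 0
    return repl, gain


def build_path_graph(read: str, partition: ReadPartition, index: KmerIndex,
                     params: SearchParams) -> PathGraph:
    """Run bridge searches for all selected pairs and assemble the graph.

    Weight-0 arcs connect consecutive positions inside a run (original
    bases).  Every weak-region boundary left uncrossed by a found bridge
    receives a dummy arc weighted by the region length, its replacement
    improved by one-sided flank extensions when they succeed.
    """
    k = index.spec.k
    positions = [p for run in partition.runs
                 for p in range(run.start, run.end)]
    arcs: List[PathGraphArc] = []
    for run in partition.runs:
        for p in range(run.start, run.end - 1):
            arcs.append(PathGraphArc(p, p + 1, 0, read[p : p + 1 + k]))

    bridges: List[PathGraphArc] = []
    for p, q, action in select_pairs(partition, params):
        if action != SEARCH:
            continue
        res = bridge_search(read[p : p + k], read[q : q + k],
                            read[p : q + k], index, params)
        if res.status is SearchStatus.FOUND:
            bridges.append(PathGraphArc(p, q, res.edit_dist, res.path_seq))
    arcs.extend(bridges)

    for left_run, right_run in zip(partition.runs, partition.runs[1:]):
        p = left_run.end - 1
        q = right_run.start
        if any(a.src_pos <= p and a.dst_pos >= q for a in bridges):
            continue
        region_len = q + k - p
        repl, gain = _one_sided_fallback(read, p, q, index, params)
        weight = max(1, region_len - gain)
        arcs.append(PathGraphArc(p, q, weight, repl, dummy=True))

    return PathGraph(positions=positions, arcs=arcs)


def shortest_correction(pg: PathGraph) -> List[PathGraphArc]:
    """Minimum-weight path from the first to the last solid position.

    The path graph is a DAG (arcs go strictly forward in the read), so the
    shortest path is solved by relaxation in position order.  Ties are
    broken by fewer arcs, then by the lexicographically earliest node
    position sequence.
    """
    if not pg.positions:
        return []
    first, last = pg.positions[0], pg.positions[-1]
    if first == last:
        return []
    arcs_by_src: Dict[int, List[PathGraphArc]] = {}
    for a in sorted(pg.arcs, key=lambda a: (a.src_pos, a.dst_pos, a.weight,
                                            a.dummy, a.replacement)):
        arcs_by_src.setdefault(a.src_pos, []).append(a)

    # node -> (cost, n_arcs, position tuple, arc list)
    best: Dict[int, Tuple[int, int, Tuple[int, ...], List[PathGraphArc]]] = {
        first: (0, 0, (first,), [])
    }
    for pos in pg.positions:
        state = best.get(pos)
        if state is None:
            continue
        cost, narcs, ptuple, arclist = state
        for a in arcs_by_src.get(pos, []):
            cand = (cost + a.weight, narcs + 1, ptuple + (a.dst_pos,))
            cur = best.get(a.dst_pos)
            if cur is None or cand < cur[:3]:
                best[a.dst_pos] = cand + (arclist + [a],)
    if last not in best:
        raise RuntimeError("path graph invariant violated: sink unreachable")
    return best[last][3]


def _splice(seq: str, first: int, last: int, k: int,
            arcs: List[PathGraphArc]) -> str:
    """Reassemble the read from chosen arcs; flanks outside stay unchanged."""
    parts = [seq[:first]]
    for i, a in enumerate(arcs):
        parts.append(a.replacement if i == 0 else a.replacement[k:])
    parts.append(seq[last + k :])
    return "".join(parts)


def _correct_head_tail(seq: str, index: KmerIndex,
                       params: SearchParams) -> str:
    k = index.spec.k
    span = params.max_region_span

    part = partition_read(seq, index)
    if part.runs and part.has_head:
        p0 = part.runs[0].start
        seg_start = max(0, p0 + k - span)
        segment = seq[seg_start : p0 + k]
        res = extension_search(seq[p0 : p0 + k], segment, Direction.HEAD,
                               index, params)
        if res.status is SearchStatus.FOUND:
            kept = segment[: len(segment) - res.segment_consumed]
            seq = seq[:seg_start] + kept + res.trimmed_seq + seq[p0 + k :]

    part = partition_read(seq, index)
    if part.runs and part.has_tail:
        pl = part.runs[-1].end - 1
        segment = seq[pl : pl + span]
        res = extension_search(seq[pl : pl + k], segment, Direction.TAIL,
                               index, params)
        if res.status is SearchStatus.FOUND:
            rest = segment[res.segment_consumed :]
            seq = seq[:pl] + res.trimmed_seq + rest + seq[pl + len(segment) :]
    return seq


def _one_pass(seq: str, index: KmerIndex, params: SearchParams) -> str:
    part = partition_read(seq, index)
    if not part.runs:
        return seq
    seq = _correct_head_tail(seq, index, params)
    part = partition_read(seq, index)
    if not part.runs:
        return seq
    pg = build_path_graph(seq, part, index, params)
    arcs = shortest_correction(pg)
    if not arcs:
        return seq
    k = index.spec.k
    return _splice(seq, pg.positions[0], pg.positions[-1], k, arcs)


def correct_read(read: str, index: KmerIndex, params: SearchParams,
                 name: str = "read") -> CorrectedRead:
    """Correct one long read with two directional passes.

    A read without a single solid k-mer cannot be anchored in the graph:
    it is flagged as skipped and passed through in lower case.  Otherwise
    each pass corrects head/tail by extension and inner regions via the
    path graph; the second pass repeats the procedure on the reverse
    complement of the first pass's output.  The final sequence is case
    encoded from its per-base solidity.
    """
    seq = read.upper()
    part = partition_read(seq, index)
    if not part.runs:
        return CorrectedRead(name=name, seq=read.lower(), skipped=True)
    seq = _one_pass(seq, index, params)
    seq = reverse_complement(_one_pass(reverse_complement(seq), index, params))
    final_part = partition_read(seq, index)
    mask = solid_positions(final_part)
    encoded = "".join(c.upper() if m else c.lower()
                      for c, m in zip(seq, mask))
    return CorrectedRead(name=name, seq=encoded, skipped=False)
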