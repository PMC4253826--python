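"""Bounded depth-first path search in the de Bruijn graph.

Two search modes share the same machinery.  A *bridge* search looks for a
path between a source and a target solid k-mer whose spelled sequence
minimises the edit distance to the weak read region between them.  An
*extension* search grows a path from a single anchor into a head or tail
region, maximising the corrected prefix length, and afterwards trims the
path back to the prefix with the best alignment score.

Both searches extend the current path one base at a time and carry, per
DFS frame, one row of the edit-distance dynamic-programming matrix against
the region sequence; a child row is derived from its parent row in O(m)
with vectorised NumPy passes.  A branch is abandoned as soon as the row
minimum exceeds the error budget, since no extension can recover.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import edlib
import numpy as np

from .dbg import KmerIndex, reverse_complement, successors


class SearchStatus(enum.Enum):
    FOUND = "FOUND"
    NO_PATH = "NO_PATH"
    ABORTED = "ABORTED"


class Direction(enum.Enum):
    HEAD = "head"
    TAIL = "tail"


@dataclass(frozen=True)
class SearchParams:
    """Knobs bounding the graph search.

    max_error_rate caps the edit distance of a correction relative to the
    region length; branching_limit caps how many non-first alternatives the
    DFS may take before the whole search aborts; target_count is the number
    of downstream solid k-mers tried as targets per source; max_region_span
    rejects source/target pairs too distant in the read for the DP to be
    worthwhile.
    """

    max_error_rate: float = 0.4
    branching_limit: int = 200
    target_count: int = 5
    max_region_span: int = 500

    def __post_init__(self) -> None:
        if not 0 < self.max_error_rate <= 1:
            raise ValueError("max_error_rate must be in (0, 1]")
        if self.branching_limit < 1:
            raise ValueError("branching_limit must be >= 1")
        if self.target_count < 1:
            raise ValueError("target_count must be >= 1")
        if self.max_region_span < 1:
            raise ValueError("max_region_span must be >= 1")


@dataclass
class BridgeResult:
    status: SearchStatus
    path_seq: Optional[str] = None
    edit_dist: Optional[int] = None


@dataclass
class ExtensionResult:
    status: SearchStatus
    path_seq: Optional[str] = None
    trimmed_seq: Optional[str] = None
    score: Optional[int] = None
    segment_consumed: int = 0  # bases of the segment covered by trimmed_seq


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b)["editDistance"]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _advance_row(row: np.ndarray, base: int, region: np.ndarray,
                 idx: np.ndarray) -> np.ndarray:
    """DP row for path+base given the row for path, against ``region``."""
    new = np.empty_like(row)
    new[0] = row[0] + 1
    np.minimum(row[1:] + 1, row[:-1] + (region != base), out=new[1:])
    # propagate gaps in the path left-to-right:
    # new[j] = min over i<=j of new[i] + (j - i)
    np.minimum(new, np.minimum.accumulate(new - idx) + idx, out=new)
    return new


def _initial_row(anchor: str, region: np.ndarray, idx: np.ndarray) -> np.ndarray:
    row = idx.astype(np.int32)
    for ch in anchor:
        row = _advance_row(row, ord(ch), region, idx)
    return row


def bridge_search(source: str, target: str, region: str, index: KmerIndex,
                  params: SearchParams) -> BridgeResult:
    """Best DBG path from ``source`` to ``target`` against ``region``.

    ``region`` must begin with the source k-mer and end with the target
    k-mer.  Among all paths explored before the branching limit, the one
    with minimal edit distance to the region is returned, provided the
    distance stays within ceil(max_error_rate * |region|).  Ties go to the
    earliest path in A<C<G<T discovery order.
    """
    k = index.spec.k
    source = source.upper()
    target = target.upper()
    region = region.upper()
    if len(source) != k or len(target) != k:
        raise ValueError("source and target must be k-mers")
    if len(region) < 2 * k:
        raise ValueError("region must contain non-overlapping anchors")
    if not region.startswith(source) or not region.endswith(target):
        raise ValueError("region must start with source and end with target")

    m = len(region)
    budget = math.ceil(params.max_error_rate * m)
    max_len = m + budget
    region_arr = _encode(region)
    idx = np.arange(m + 1, dtype=np.int32)

    row0 = _initial_row(source, region_arr, idx)
    best_dist: Optional[int] = None
    best_seq: Optional[str] = None

    path: List[str] = [source]  # chunks: source then single bases
    # frame: [children list, next child index, parent row]
    stack: List[list] = [[successors(source, index), 0, row0]]
    branch_events = 0
    path_len = k

    while stack:
        frame = stack[-1]
        children, ci, row = frame
        if ci >= len(children):
            stack.pop()
            if stack:
                path.pop()
                path_len -= 1
            continue
        frame[1] += 1
        if ci >= 1:
            branch_events += 1
            if branch_events > params.branching_limit:
                return BridgeResult(status=SearchStatus.ABORTED)
        child = children[ci]
        if path_len + 1 > max_len:
            continue
        new_row = _advance_row(row, ord(child[-1]), region_arr, idx)
        if int(new_row.min()) > budget:
            continue
        if child == target:
            d = int(new_row[-1])
            if d <= budget and (best_dist is None or d < best_dist):
                best_dist = d
                best_seq = "".join(path) + child[-1]
            continue  # stop this branch at the target
        path.append(child[-1])
        path_len += 1
        stack.append([successors(child, index), 0, new_row])

    if best_dist is None:
        return BridgeResult(status=SearchStatus.NO_PATH)
    return BridgeResult(status=SearchStatus.FOUND, path_seq=best_seq,
                        edit_dist=best_dist)


def best_prefix_alignment(path_seq: str, segment: str,
                          min_len: int = 1) -> Tuple[int, int, int]:
    """Best-scoring prefix of ``path_seq`` against any prefix of ``segment``.

    Global alignment scoring: match +1, mismatch -1, gap -1.  Returns
    (trimmed length, score, segment bases consumed); ties are broken toward
    the longer path prefix, then the longer segment prefix.  Both strings
    must begin with the anchor k-mer; ``min_len`` keeps the trimmed prefix
    from dropping below the anchor length.
    """
    if not path_seq:
        raise ValueError("empty path sequence")
    min_len = min(min_len, len(path_seq))
    m = len(segment)
    seg_arr = _encode(segment)
    idx = np.arange(m + 1, dtype=np.int32)
    row = -idx.astype(np.int32)

    best: Optional[Tuple[int, int, int]] = None  # (score, i, j)
    for i, ch in enumerate(path_seq, start=1):
        new = np.empty_like(row)
        new[0] = -i
        match = np.where(seg_arr == ord(ch), 1, -1).astype(np.int32)
        np.maximum(row[:-1] + match, row[1:] - 1, out=new[1:])
        np.maximum(new, np.maximum.accumulate(new + idx) - idx, out=new)
        row = new
        if i < min_len:
            continue
        sc = int(row.max())
        j = m - int(np.argmax(row[::-1]))  # last (longest) argmax
        if best is None or (sc, i, j) > best:
            best = (sc, i, j)
    assert best is not None
    score, i, j = best
    return i, score, j


def _tail_extension(anchor: str, segment: str, index: KmerIndex,
                    params: SearchParams) -> ExtensionResult:
    k = index.spec.k
    m = len(segment)
    budget_len = m + math.ceil(params.max_error_rate * m)
    seg_arr = _encode(segment)
    idx = np.arange(m + 1, dtype=np.int32)
    row0 = _initial_row(anchor, seg_arr, idx)

    rate = params.max_error_rate
    best_len = 0
    best_minrow = 0
    best_seq: Optional[str] = None

    path: List[str] = [anchor]
    stack: List[list] = [[successors(anchor, index), 0, row0]]
    branch_events = 0
    path_len = k

    while stack:
        frame = stack[-1]
        children, ci, row = frame
        if ci >= len(children):
            stack.pop()
            if stack:
                path.pop()
                path_len -= 1
            continue
        frame[1] += 1
        if ci >= 1:
            branch_events += 1
            if branch_events > params.branching_limit:
                return ExtensionResult(status=SearchStatus.ABORTED)
        child = children[ci]
        if path_len + 1 > budget_len:
            continue
        new_row = _advance_row(row, ord(child[-1]), seg_arr, idx)
        mr = int(new_row.min())
        if mr > rate * (path_len + 1):
            continue  # drop-off: too many errors for the bases consumed
        path.append(child[-1])
        path_len += 1
        if path_len > best_len or (path_len == best_len and mr < best_minrow):
            best_len = path_len
            best_minrow = mr
            best_seq = "".join(path)
        stack.append([successors(child, index), 0, new_row])

    if best_seq is None:
        return ExtensionResult(status=SearchStatus.NO_PATH)
    trim_len, score, consumed = best_prefix_alignment(best_seq, segment,
                                                      min_len=k)
    return ExtensionResult(
        status=SearchStatus.FOUND,
        path_seq=best_seq,
        trimmed_seq=best_seq[:trim_len],
        score=score,
        segment_consumed=consumed,
    )


def extension_search(anchor: str, segment: str, direction: Direction,
                     index: KmerIndex, params: SearchParams) -> ExtensionResult:
    """One-anchor search correcting a prefix of a head/tail region.

    In the TAIL direction ``segment`` must begin with the anchor k-mer.
    The HEAD direction is served by reverse-complementing anchor and
    segment (which must then *end* with the anchor), searching as a tail
    and reverse-complementing the result; segment_consumed then counts
    bases from the segment's end.
    """
    anchor = anchor.upper()
    segment = segment.upper()
    k = index.spec.k
    if len(anchor) != k:
        raise ValueError("anchor must be a k-mer")
    if direction is Direction.HEAD:
        if not segment.endswith(anchor):
            raise ValueError("head segment must end with the anchor k-mer")
        res = _tail_extension(reverse_complement(anchor),
                              reverse_complement(segment), index, params)
        if res.status is SearchStatus.FOUND:
            res.path_seq = reverse_complement(res.path_seq)
            res.trimmed_seq = reverse_complement(res.trimmed_seq)
        return res
    if not segment.startswith(anchor):
        raise ValueError("tail segment must start with the anchor k-mer")
    return _tail_extension(anchor, segment, index, params)
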