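"""Independent oracles used by the tests.

Everything here deliberately avoids the package's own code paths: k-mer
counting by a direct double loop (reverse complements via Biopython),
edit distance by a plain full-matrix DP, graph searches by exhaustive
enumeration.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

from Bio.Seq import Seq


def bio_revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def naive_kmer_count(reads: Sequence[str], k: int) -> Dict[str, int]:
    """Direct double-loop canonical k-mer count (N windows skipped)."""
    counts: Dict[str, int] = {}
    for read in reads:
        seq = read.upper()
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if set(km) - set("ACGT"):
                continue
            rc = bio_revcomp(km)
            c = min(km, rc)
            counts[c] = counts.get(c, 0) + 1
    return counts


def levenshtein(a: str, b: str) -> int:
    """Plain quadratic unit-cost edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def enumerate_bridge_paths(index, source: str, target: str, max_len: int,
                           cap: int = 10_000,
                           node_budget: int = 200_000) -> Optional[List[str]]:
    """All DBG walks source -> target (target terminal), length <= max_len.

    Mirrors the bridge-search contract: a walk ends at the first time the
    target k-mer is reached after at least one extension.  Returns None if
    more than ``cap`` walks exist or the recursion visits more than
    ``node_budget`` nodes (instance too large to enumerate).
    """
    from hybridec.dbg import successors

    paths: List[str] = []
    visited = [0]

    def rec(node: str, spelled: List[str]) -> bool:
        visited[0] += 1
        if len(paths) > cap or visited[0] > node_budget:
            return False
        if len(spelled) + len(source) >= max_len:
            return True  # cannot extend further
        for child in successors(node, index):
            nxt = spelled + [child[-1]]
            if child == target:
                paths.append(source + "".join(nxt))
                if len(paths) > cap:
                    return False
                continue
            if not rec(child, nxt):
                return False
        return True

    ok = rec(source, [])
    return paths if ok else None


def best_bridge_by_enumeration(index, source: str, target: str, region: str,
                               budget: int,
                               cap: int = 10_000) -> Optional[Tuple[int, str]]:
    """(min distance, earliest minimal path) over the exhaustive walk set."""
    paths = enumerate_bridge_paths(index, source, target,
                                   max_len=len(region) + budget, cap=cap)
    if paths is None:
        raise RuntimeError("instance too large for the enumeration oracle")
    best: Optional[Tuple[int, str]] = None
    for p in paths:  # discovery order of the recursion = A<C<G<T DFS order
        d = levenshtein(p, region)
        if d <= budget and (best is None or d < best[0]):
            best = (d, p)
    return best


def brute_force_shortest(positions: Sequence[int], arcs) -> Tuple:
    """Min (weight, n_arcs, node tuple) path over exhaustive enumeration."""
    first, last = positions[0], positions[-1]
    by_src: Dict[int, list] = {}
    for a in arcs:
        by_src.setdefault(a.src_pos, []).append(a)
    best: List[Optional[Tuple]] = [None]

    def rec(pos: int, w: int, n: int, nodes: Tuple[int, ...]) -> None:
        if pos == last:
            key = (w, n, nodes)
            if best[0] is None or key < best[0]:
                best[0] = key
            return
        for a in by_src.get(pos, []):
            rec(a.dst_pos, w + a.weight, n + 1, nodes + (a.dst_pos,))

    rec(first, 0, 0, (first,))
    if best[0] is None:
        raise RuntimeError("no path in brute-force oracle")
    return best[0]
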