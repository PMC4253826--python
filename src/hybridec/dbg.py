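"""De Bruijn graph over solid canonical k-mers counted from short reads.

The graph is never materialised: nodes are the canonical k-mers whose count
in the short-read set reaches the solidity threshold, and arcs (k-1 base
overlaps) are discovered on the fly by querying the four possible one-base
extensions of a k-mer.  Because read strands are unknown, a node stands for
a k-mer *and* its reverse complement; all count lookups go through the
canonical (lexicographically smaller) form while traversal stays in the
orientation of the query.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Dict, Iterable, List

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_BASES = "ACGT"
_VALID = frozenset(_BASES)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class KmerSpec:
    """Parameters defining k-mer solidity.

    k must be odd so that no k-mer equals its own reverse complement and
    the canonical form is always a strict choice between the two strands.
    ``require_arcs`` adds the refinement that a solid k-mer must also have
    at least one incoming and one outgoing arc in the graph.
    """

    k: int = 19
    solid_threshold: int = 3
    require_arcs: bool = True

    def __post_init__(self) -> None:
        if self.k < 3 or self.k % 2 == 0:
            raise ValueError(f"k must be an odd integer >= 3, got {self.k}")
        if self.solid_threshold < 1:
            raise ValueError(
                f"solid_threshold must be >= 1, got {self.solid_threshold}"
            )


@dataclass
class KmerIndex:
    """Counts of canonical k-mers from a short-read set."""

    spec: KmerSpec
    counts: Dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.counts)

    def count(self, kmer: str) -> int:
        """Occurrence count of ``kmer`` (either strand), 0 if unseen."""
        return self.counts.get(canonical(kmer), 0)


def _check_kmer(seq_k: str, k: int | None = None) -> str:
    seq_k = seq_k.upper()
    if k is not None and len(seq_k) != k:
        raise ValueError(f"expected a {k}-mer, got length {len(seq_k)}")
    if not seq_k or set(seq_k) - _VALID:
        raise ValueError(f"k-mer contains non-ACGT characters: {seq_k!r}")
    return seq_k


def canonical(seq_k: str, k: int | None = None) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement.

    Idempotent and strand-symmetric: canonical(rc(x)) == canonical(x).
    """
    seq_k = _check_kmer(seq_k, k)
    rc = seq_k.translate(_COMPLEMENT)[::-1]
    return seq_k if seq_k <= rc else rc


def count_kmers(short_reads: Iterable[str], spec: KmerSpec) -> KmerIndex:
    """Count canonical k-mers over all k-length windows of the reads.

    Windows containing a non-ACGT character (e.g. N) are skipped; reads
    shorter than k contribute nothing.  Input case is ignored.
    """
    k = spec.k
    counts: Dict[str, int] = {}
    for read in short_reads:
        seq = read.upper()
        n = len(seq)
        if n < k:
            continue
        bad = [i for i, c in enumerate(seq) if c not in _VALID]
        bi = 0
        nbad = len(bad)
        for i in range(n - k + 1):
            while bi < nbad and bad[bi] < i:
                bi += 1
            if bi < nbad and bad[bi] < i + k:
                continue
            km = seq[i : i + k]
            rc = km.translate(_COMPLEMENT)[::-1]
            c = km if km <= rc else rc
            counts[c] = counts.get(c, 0) + 1
    return KmerIndex(spec=spec, counts=counts)


def _count_passes(kmer: str, index: KmerIndex) -> bool:
    rc = kmer.translate(_COMPLEMENT)[::-1]
    c = kmer if kmer <= rc else rc
    return index.counts.get(c, 0) >= index.spec.solid_threshold


def is_solid(kmer: str, index: KmerIndex) -> bool:
    """Whether a k-mer is solid: count >= threshold, plus (optionally) arcs.

    With ``require_arcs`` the k-mer must additionally have at least one
    left and one right one-base extension passing the count threshold.
    Extensions are evaluated in the orientation of the query; only the
    count lookup canonicalises.
    """
    kmer = _check_kmer(kmer, index.spec.k)
    if not _count_passes(kmer, index):
        return False
    if not index.spec.require_arcs:
        return True
    core_r = kmer[1:]
    core_l = kmer[:-1]
    has_out = any(_count_passes(core_r + b, index) for b in _BASES)
    if not has_out:
        return False
    return any(_count_passes(b + core_l, index) for b in _BASES)


def successors(kmer: str, index: KmerIndex) -> List[str]:
    """Solid-by-count right neighbours, in appended-base order A<C<G<T.

    Results are reported in the orientation extending the query.
    """
    kmer = _check_kmer(kmer, index.spec.k)
    core = kmer[1:]
    return [core + b for b in _BASES if _count_passes(core + b, index)]


def predecessors(kmer: str, index: KmerIndex) -> List[str]:
    """Solid-by-count left neighbours, in prepended-base order A<C<G<T."""
    kmer = _check_kmer(kmer, index.spec.k)
    core = kmer[:-1]
    return [b + core for b in _BASES if _count_passes(b + core, index)]


def save_index(index: KmerIndex, path: str) -> None:
    """Write a flat ``kmer<TAB>count`` file (gzip if path ends in .gz)."""
    op = gzip.open if str(path).endswith(".gz") else open
    with op(path, "wt") as fh:
        fh.write(f"#k={index.spec.k}\tsolid_threshold={index.spec.solid_threshold}"
                 f"\trequire_arcs={int(index.spec.require_arcs)}\n")
        for km in sorted(index.counts):
            fh.write(f"{km}\t{index.counts[km]}\n")


def load_index(path: str) -> KmerIndex:
    """Read back an index written by :func:`save_index`."""
    op = gzip.open if str(path).endswith(".gz") else open
    with op(path, "rt") as fh:
        header = fh.readline().strip()
        if not header.startswith("#k="):
            raise ValueError("missing index header line")
        fields = dict(f.split("=", 1) for f in header[1:].split("\t"))
        spec = KmerSpec(
            k=int(fields["k"]),
            solid_threshold=int(fields["solid_threshold"]),
            require_arcs=bool(int(fields.get("require_arcs", "1"))),
        )
        counts: Dict[str, int] = {}
        for line in fh:
            km, cnt = line.split("\t")
            counts[km] = int(cnt)
    return KmerIndex(spec=spec, counts=counts)
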