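"""Partition of a long read into solid runs and weak regions.

Every k-mer start position of a read is classified solid or weak against
the short-read index; maximal runs of solid positions are the anchors from
which corrective graph searches start.  Weak regions touching a read end
(head/tail) have a single anchor; inner weak regions are flanked by a run
on each side.  All coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .dbg import KmerIndex, is_solid

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class SolidRun:
    """Maximal run of solid k-mer start positions, half-open [start, end)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("SolidRun requires start < end")


@dataclass
class ReadPartition:
    read: str
    k: int
    runs: List[SolidRun]

    @property
    def n_positions(self) -> int:
        """Number of k-mer start positions in the read (0 if |read| < k)."""
        return max(0, len(self.read) - self.k + 1)

    @property
    def has_head(self) -> bool:
        """Weak span before the first solid k-mer."""
        return bool(self.runs) and self.runs[0].start > 0

    @property
    def has_tail(self) -> bool:
        """Weak span after the last base covered by a solid k-mer."""
        return bool(self.runs) and self.runs[-1].end - 1 + self.k < len(self.read)

    @property
    def inner_spans(self) -> List[Tuple[int, int]]:
        """Weak k-mer position spans between consecutive runs (half-open)."""
        return [
            (a.end, b.start) for a, b in zip(self.runs, self.runs[1:])
        ]

    @property
    def inner_base_spans(self) -> List[Tuple[int, int]]:
        """Base intervals between runs not covered by any flanking solid k-mer."""
        return [
            (a.end - 1 + self.k, b.start)
            for a, b in zip(self.runs, self.runs[1:])
        ]

    def solid_flags(self) -> np.ndarray:
        """Boolean vector over k-mer start positions (True = solid)."""
        flags = np.zeros(self.n_positions, dtype=bool)
        for run in self.runs:
            flags[run.start : run.end] = True
        return flags


def partition_read(read: str, index: KmerIndex) -> ReadPartition:
    """Classify every k-mer position of ``read`` and collect maximal runs.

    Reads shorter than k (or with no solid k-mer) yield an empty run list;
    the caller decides whether to skip them.
    """
    k = index.spec.k
    read = read.upper()
    n = len(read) - k + 1
    runs: List[SolidRun] = []
    start: Optional[int] = None
    for i in range(max(0, n)):
        km = read[i : i + k]
        solid = not (set(km) - _VALID) and is_solid(km, index)
        if solid and start is None:
            start = i
        elif not solid and start is not None:
            runs.append(SolidRun(start, i))
            start = None
    if start is not None:
        runs.append(SolidRun(start, n))
    return ReadPartition(read=read, k=k, runs=runs)


def solid_positions(partition: ReadPartition) -> np.ndarray:
    """Per-base solidity: base i is solid iff some solid k-mer covers it."""
    mask = np.zeros(len(partition.read), dtype=bool)
    k = partition.k
    for run in partition.runs:
        mask[run.start : run.end - 1 + k] = True
    return mask
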