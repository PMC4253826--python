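"""Synthetic genomes, short reads and long reads with ground truth.

The long-read error process emulates the SMRT profile: a high per-base
error rate (~15%) dominated by insertions, then deletions, then
substitutions, with errors independent of sequence context.  Short reads
carry a low substitution-only error rate at high coverage.  Every long
read records the exact list of edits applied to its source genome
interval, so correction accuracy can be evaluated without any mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .dbg import reverse_complement

_BASES = "ACGT"

# edit ops: ("I", pos, base)   insert base before oriented-region position pos
#           ("D", pos, base)   region base at pos (== base) absent from read
#           ("S", pos, "X>Y")  region base X replaced by read base Y
Edit = Tuple[str, int, str]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic data.

    Defaults: a 50 kb random genome; 75 bp short reads at 50x coverage with
    0.5% substitutions; long reads of 2-8 kb at 2x coverage with 15% errors
    split 55% insertion / 30% deletion / 15% substitution.
    """

    genome_length: int = 50_000
    gc: float = 0.5
    sr_coverage: float = 50.0
    sr_length: int = 75
    sr_sub_rate: float = 0.005
    lr_coverage: float = 2.0
    lr_error_rate: float = 0.15
    lr_ins_frac: float = 0.55
    lr_del_frac: float = 0.30
    lr_sub_frac: float = 0.15
    lr_length_range: Tuple[int, int] = (2_000, 8_000)
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("gc", "sr_sub_rate", "lr_error_rate", "lr_ins_frac",
                     "lr_del_frac", "lr_sub_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        total = self.lr_ins_frac + self.lr_del_frac + self.lr_sub_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError("lr_ins/del/sub fractions must sum to 1")
        lo, hi = self.lr_length_range
        if lo > hi or lo < 1:
            raise ValueError("invalid lr_length_range")


@dataclass
class LrTruth:
    """Provenance of one simulated long read.

    ``start``/``end`` are 0-based half-open genome coordinates; edits are
    expressed against the *oriented* region (the genome substring, reverse
    complemented when strand is '-') and, replayed in order, reproduce the
    read exactly.
    """

    name: str
    start: int
    end: int
    strand: str
    edits: List[Edit] = field(default_factory=list)

    def oriented_region(self, genome: str) -> str:
        region = genome[self.start : self.end]
        return region if self.strand == "+" else reverse_complement(region)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(stream,))
    )


def simulate_genome(cfg: SimConfig) -> str:
    """Random genome with i.i.d. bases at the requested GC content."""
    rng = _rng(cfg, 0)
    at = (1.0 - cfg.gc) / 2.0
    gcp = cfg.gc / 2.0
    draws = rng.choice(4, size=cfg.genome_length, p=[at, gcp, gcp, at])
    return "".join(_BASES[i] for i in draws)


def simulate_short_reads(genome: str, cfg: SimConfig, with_truth: bool = False):
    """Uniformly placed stranded short reads with substitution errors.

    With ``with_truth`` also returns, per read, its (start, strand,
    substituted-position list) placement record.
    """
    if not genome:
        raise ValueError("genome must be non-empty")
    rng = _rng(cfg, 1)
    n_reads = int(round(cfg.sr_coverage * len(genome) / cfg.sr_length))
    length = min(cfg.sr_length, len(genome))
    reads: List[str] = []
    placements: List[Tuple[int, str, List[int]]] = []
    for _ in range(n_reads):
        start = int(rng.integers(0, len(genome) - length + 1))
        seq = genome[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = reverse_complement(seq)
        subs: List[int] = []
        if cfg.sr_sub_rate > 0:
            chars = list(seq)
            hits = np.nonzero(rng.random(length) < cfg.sr_sub_rate)[0]
            for i in hits:
                alts = _BASES.replace(chars[i], "")
                chars[i] = alts[int(rng.integers(0, 3))]
                subs.append(int(i))
            seq = "".join(chars)
        reads.append(seq)
        placements.append((start, strand, subs))
    if with_truth:
        return reads, placements
    return reads


def _mutate(region: str, cfg: SimConfig,
            rng: np.random.Generator) -> Tuple[str, List[Edit]]:
    out: List[str] = []
    edits: List[Edit] = []
    e = cfg.lr_error_rate
    t_ins = cfg.lr_ins_frac
    t_del = t_ins + cfg.lr_del_frac
    for i, base in enumerate(region):
        if rng.random() < e:
            u = rng.random()
            if u < t_ins:
                b = _BASES[int(rng.integers(0, 4))]
                edits.append(("I", i, b))
                out.append(b)
                out.append(base)
            elif u < t_del:
                edits.append(("D", i, base))
            else:
                alts = _BASES.replace(base, "")
                b = alts[int(rng.integers(0, 3))]
                edits.append(("S", i, f"{base}>{b}"))
                out.append(b)
        else:
            out.append(base)
    return "".join(out), edits


def simulate_long_reads(
    genome: str, cfg: SimConfig
) -> Tuple[List[Tuple[str, str]], List[LrTruth]]:
    """Long reads with per-base indel-dominated errors plus ground truth."""
    lo, hi = cfg.lr_length_range
    if len(genome) < hi:
        raise ValueError("genome shorter than the maximum read length")
    rng = _rng(cfg, 2)
    mean_len = (lo + hi) / 2.0
    n_reads = int(round(cfg.lr_coverage * len(genome) / mean_len))
    reads: List[Tuple[str, str]] = []
    truths: List[LrTruth] = []
    for i in range(n_reads):
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, len(genome) - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        truth = LrTruth(name=f"lr_{i}", start=start, end=start + length,
                        strand=strand)
        region = truth.oriented_region(genome)
        seq, edits = _mutate(region, cfg, rng)
        truth.edits = edits
        reads.append((truth.name, seq))
        truths.append(truth)
    return reads, truths


def apply_edits(region: str, edits: Sequence[Edit]) -> str:
    """Replay truth edits on the oriented region, reproducing the read."""
    ins: Dict[int, List[str]] = {}
    other: Dict[int, Edit] = {}
    for op, pos, payload in edits:
        if op == "I":
            ins.setdefault(pos, []).append(payload)
        else:
            other[pos] = (op, pos, payload)
    out: List[str] = []
    for i in range(len(region) + 1):
        out.extend(ins.get(i, ()))
        if i == len(region):
            break
        if i in other:
            op, _, payload = other[i]
            if op == "D":
                continue
            out.append(payload.split(">")[1])
        else:
            out.append(region[i])
    return "".join(out)


def invert_edits(read: str, edits: Sequence[Edit]) -> str:
    """Reconstruct the oriented genome region from a read and its edits."""
    ins: Dict[int, int] = {}
    other: Dict[int, Edit] = {}
    n_ins = n_del = 0
    for op, pos, payload in edits:
        if op == "I":
            ins[pos] = ins.get(pos, 0) + 1
            n_ins += 1
        else:
            other[pos] = (op, pos, payload)
            n_del += op == "D"
    region_len = len(read) - n_ins + n_del
    region: List[str] = []
    ri = 0  # read cursor
    for pos in range(region_len):
        ri += ins.get(pos, 0)  # skip inserted read bases
        if pos in other:
            op, _, payload = other[pos]
            if op == "D":
                region.append(payload)
            else:
                region.append(payload.split(">")[0])
                ri += 1
        else:
            region.append(read[ri])
            ri += 1
    return "".join(region)


def write_truth(truths: Sequence[LrTruth], path: str) -> None:
    """Tab-separated sidecar: name, start, end, strand, edit list."""
    with open(path, "w") as fh:
        fh.write("name\tstart\tend\tstrand\tedits\n")
        for t in truths:
            enc = ";".join(f"{op}:{pos}:{payload}"
                           for op, pos, payload in t.edits) or "-"
            fh.write(f"{t.name}\t{t.start}\t{t.end}\t{t.strand}\t{enc}\n")


def read_truth(path: str) -> List[LrTruth]:
    truths: List[LrTruth] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("name\t"):
            raise ValueError("missing truth header line")
        for line in fh:
            name, start, end, strand, enc = line.rstrip("\n").split("\t")
            edits: List[Edit] = []
            if enc != "-":
                for item in enc.split(";"):
                    op, pos, payload = item.split(":", 2)
                    edits.append((op, int(pos), payload))
            truths.append(LrTruth(name=name, start=int(start), end=int(end),
                                  strand=strand, edits=edits))
    return truths
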