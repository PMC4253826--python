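"""Position-level correction accuracy: TP/FP/TN/FN, Sensitivity and Gain.

The three-way correspondence between original read, corrected read and the
true genomic region is anchored on the truth coordinates: each truth
position yields one column, and inserted read bases between truth
positions yield extra columns.  A column is

* TP when the original read was erroneous there and the corrected read is
  correct,
* FN when the error remains,
* FP when the corrector damaged a previously correct position,
* TN when both are correct.

Sensitivity = TP / (TP + FN) measures how many errors were recognised;
Gain = (TP - FP) / (TP + FN) additionally penalises introduced errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from .simulate import Edit

_CIGAR_OPS = frozenset("=XID")


@dataclass
class EvalCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp,
                          self.tn + other.tn, self.fn + other.fn)

    @property
    def columns(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def sensitivity(c: EvalCounts) -> float:
    """TP / (TP + FN); undefined when the original read had no errors."""
    if c.tp + c.fn == 0:
        raise ValueError("sensitivity undefined: no erroneous positions")
    return c.tp / (c.tp + c.fn)


def gain(c: EvalCounts) -> float:
    """(TP - FP) / (TP + FN); negative when more errors are added than fixed."""
    if c.tp + c.fn == 0:
        raise ValueError("gain undefined: no erroneous positions")
    return (c.tp - c.fp) / (c.tp + c.fn)


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch not in _CIGAR_OPS:
                raise ValueError(f"unexpected cigar op {ch!r}")
            yield int(num), ch
            num = ""


def _states_from_alignment(query: str,
                           truth: str) -> Tuple[np.ndarray, Dict[int, int]]:
    """Per-truth-position error flags and insertion counts for a read.

    Uses a deterministic global alignment (edlib, extended cigar).  A truth
    position is erroneous when mismatched or deleted from the query; 'I'
    operations record inserted query bases in the slot before the current
    truth position.
    """
    err = np.zeros(len(truth), dtype=bool)
    ins: Dict[int, int] = {}
    if not query:
        raise ValueError("empty query; caller must special-case")
    res = edlib.align(query, truth, task="path", mode="NW")
    ti = 0
    for n, op in _parse_cigar(res["cigar"]):
        if op == "=":
            ti += n
        elif op == "X":
            err[ti : ti + n] = True
            ti += n
        elif op == "D":  # truth base missing from the query
            err[ti : ti + n] = True
            ti += n
        else:  # 'I': extra query bases
            ins[ti] = ins.get(ti, 0) + n
    return err, ins


def _states_from_edits(truth_len: int,
                       edits: Sequence[Edit]) -> Tuple[np.ndarray, Dict[int, int]]:
    """Exact per-position states reconstructed from simulator truth edits."""
    err = np.zeros(truth_len, dtype=bool)
    ins: Dict[int, int] = {}
    for op, pos, _payload in edits:
        if op == "I":
            ins[pos] = ins.get(pos, 0) + 1
        else:
            err[pos] = True
    return err, ins


def classify_positions(original: str, corrected: str, truth_region: str,
                       truth_edits: Optional[Sequence[Edit]] = None) -> EvalCounts:
    """TP/FP/TN/FN over the three-way correspondence of one read.

    The original<->truth correspondence comes from the simulator's edit
    list when available (exact), otherwise from a global alignment; the
    corrected<->truth correspondence is always aligned.  An empty corrected
    read counts every original error as FN and everything else as TN.
    """
    original = original.upper()
    corrected = corrected.upper()
    if not truth_region:
        raise ValueError("truth_region must be non-empty")
    if truth_edits is not None:
        o_err, o_ins = _states_from_edits(len(truth_region), truth_edits)
    else:
        o_err, o_ins = _states_from_alignment(original, truth_region)

    if not corrected:
        n_err = int(o_err.sum()) + sum(o_ins.values())
        return EvalCounts(tp=0, fp=0, fn=n_err,
                          tn=len(truth_region) - int(o_err.sum()))

    if corrected == original:
        # identical sequences share one correspondence with the truth
        c_err, c_ins = o_err, o_ins
    else:
        c_err, c_ins = _states_from_alignment(corrected, truth_region)

    tp = int(np.sum(o_err & ~c_err))
    fn = int(np.sum(o_err & c_err))
    fp = int(np.sum(~o_err & c_err))
    tn = int(np.sum(~o_err & ~c_err))
    for slot in set(o_ins) | set(c_ins):
        no = o_ins.get(slot, 0)
        nc = c_ins.get(slot, 0)
        both = min(no, nc)
        fn += both            # insertion kept: still erroneous
        tp += max(0, no - nc)  # inserted base removed
        fp += max(0, nc - no)  # new inserted base
    return EvalCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def evaluate_reads(
    triples: Sequence[Tuple[str, str, str, Optional[Sequence[Edit]]]]
) -> Tuple[List[EvalCounts], EvalCounts]:
    """Classify a batch of (original, corrected, truth_region, edits)."""
    per_read = [classify_positions(o, c, t, e) for o, c, t, e in triples]
    total = EvalCounts()
    for c in per_read:
        total = total + c
    return per_read, total


def format_report(names: Sequence[str], per_read: Sequence[EvalCounts],
                  total: EvalCounts) -> str:
    """Tab-separated per-read report with totals, 4 decimal places."""
    lines = ["name\ttp\tfp\ttn\tfn\tsensitivity\tgain"]
    def _fmt(name: str, c: EvalCounts) -> str:
        if c.tp + c.fn > 0:
            s, g = f"{sensitivity(c):.4f}", f"{gain(c):.4f}"
        else:
            s = g = "NA"
        return f"{name}\t{c.tp}\t{c.fp}\t{c.tn}\t{c.fn}\t{s}\t{g}"
    lines.extend(_fmt(n, c) for n, c in zip(names, per_read))
    lines.append(_fmt("TOTAL", total))
    return "\n".join(lines) + "\n"
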