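"""Trimming and splitting of case-encoded corrected reads.

Corrected reads mark solid bases upper case and weak bases lower case.
``trim`` removes weak ends only; ``trim_split`` extracts every maximal
solid run as its own sequence.
"""

from __future__ import annotations

import logging
from typing import List, Tuple

from .correction import CorrectedRead

logger = logging.getLogger(__name__)


def trim(corrected: CorrectedRead) -> CorrectedRead:
    """Remove the maximal weak (lower-case) prefix and suffix.

    Weak stretches bordered by solid bases on both sides are kept.  An
    all-weak read trims to the empty sequence; the record is retained.
    """
    seq = corrected.seq
    start = 0
    end = len(seq)
    while start < end and not seq[start].isupper():
        start += 1
    while end > start and not seq[end - 1].isupper():
        end -= 1
    out = seq[start:end]
    if not out:
        logger.warning("read %s is entirely weak; trimmed to empty",
                       corrected.name)
    return CorrectedRead(name=corrected.name, seq=out,
                         skipped=corrected.skipped)


def trim_split(corrected: CorrectedRead) -> List[Tuple[str, str]]:
    """Maximal solid (upper-case) runs as (name_split<i>, sequence) pairs."""
    pieces: List[Tuple[str, str]] = []
    run_start = None
    seq = corrected.seq
    for i, c in enumerate(seq):
        if c.isupper() and run_start is None:
            run_start = i
        elif not c.isupper() and run_start is not None:
            pieces.append((f"{corrected.name}_split{len(pieces)}",
                           seq[run_start:i]))
            run_start = None
    if run_start is not None:
        pieces.append((f"{corrected.name}_split{len(pieces)}",
                       seq[run_start:]))
    return pieces
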