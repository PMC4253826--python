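"""FASTA/FASTQ reading and FASTA writing (gzip transparent)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, List, Tuple

from Bio import SeqIO

_FASTQ_EXT = {".fq", ".fastq"}
_FASTA_EXT = {".fa", ".fasta", ".fna"}


def _sniff_format(path: str) -> str:
    p = Path(path)
    suffixes = [s.lower() for s in p.suffixes]
    if suffixes and suffixes[-1] == ".gz":
        suffixes = suffixes[:-1]
    if suffixes and suffixes[-1] in _FASTQ_EXT:
        return "fastq"
    if suffixes and suffixes[-1] in _FASTA_EXT:
        return "fasta"
    raise ValueError(f"cannot infer sequence format from {path!r}")


def read_sequences(path: str) -> List[Tuple[str, str]]:
    """Read (name, sequence) pairs from FASTA/FASTQ, optionally gzipped.

    Qualities are ignored; sequences keep their input case (callers
    normalise where it matters).
    """
    fmt = _sniff_format(path)
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, fmt)]


def write_fasta(records: Iterable[Tuple[str, str]], path: str,
                wrap: int = 80) -> None:
    """Write FASTA with line wrapping; name may embed a description."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            if not seq:
                fh.write("\n")
                continue
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")
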