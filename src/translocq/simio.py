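"""FASTQ reading/writing (Phred+33) via Biopython's fast FASTQ iterator."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = ["iter_fastq", "write_fastq"]


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality) from a FASTQ file."""
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq.upper(), qual


def write_fastq(
    reads: Iterable[tuple[str, str]], path: str | Path, qual_char: str = "I"
) -> int:
    """Write (read_id, sequence) pairs as FASTQ with uniform quality."""
    n = 0
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual_char * len(seq)}\n")
            n += 1
    return n
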