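"""FASTA and structure-annotated sequence I/O.

FASTA is read/written through Biopython.  ``.gz`` paths are transparently
compressed.  The Vienna-style annotated writer emits, per record, the
header, the sequence and the dot-bracket structure on the following line.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, List, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_fasta", "write_fasta", "write_vienna"]


def _open_text(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fasta(path) -> List[Tuple[str, str]]:
    """Read (id, sequence) pairs; T is transcribed to U."""
    with _open_text(path, "r") as fh:
        return [
            (rec.id, str(rec.seq).upper().replace("T", "U"))
            for rec in SeqIO.parse(fh, "fasta")
        ]


def write_fasta(records: Iterable[Tuple[str, str]], path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with _open_text(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta-2line")


def write_vienna(
    records: Iterable[Tuple[str, str, str]], path
) -> None:
    """Write (id, sequence, dot-bracket) triples in Vienna convention."""
    with _open_text(path, "w") as fh:
        for name, seq, structure in records:
            fh.write(f">{name}\n{seq}\n{structure}\n")
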