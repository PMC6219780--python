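"""FASTA input/output for strands, databases and stego pools.

Parsing and serialisation go through Biopython; this layer adds strict
A/C/G/T validation with per-record diagnostics (the cryptosystem tolerates
no ambiguity codes) and uppercase normalisation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequence import DnaSequence

__all__ = ["read_fasta", "write_fasta"]


def read_fasta(path: str | Path) -> list[tuple[str, DnaSequence]]:
    """Read FASTA records as (id, DnaSequence) pairs.

    Raises ValueError naming the offending record if any residue is
    outside A/C/G/T (after uppercasing).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            seq = DnaSequence(str(rec.seq))
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from None
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA; sequences are validated first."""
    recs = [
        SeqRecord(Seq(str(DnaSequence(seq))), id=str(name), description="")
        for name, seq in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")
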