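"""Text / bit-string / DNA conversions under complement-consistent code tables.

Two bits encode one base.  Of the 24 bijections between {00,01,10,11} and
{A,C,G,T}, exactly 8 are *complement-consistent*: the code of a base's
Watson–Crick complement is the bitwise NOT of the base's code (A<->T,
C<->G pair with 00<->11 and 01<->10).  The scheme restricts itself to
those 8 tables; the table id (1-8) is part of the shared secret.

Text is fixed at 7-bit ASCII, serialised 8 bits per character,
most-significant bit first.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

from .sequence import DnaSequence

__all__ = [
    "CodeTable",
    "list_code_tables",
    "get_code_table",
    "text_to_bits",
    "bits_to_text",
    "bits_to_dna",
    "dna_to_bits",
]

_CODES = ("00", "01", "10", "11")


@dataclass(frozen=True)
class CodeTable:
    """Bijection between 2-bit codes and bases, addressed by its table id."""

    id: int
    encode: Mapping[str, str]  # 2-bit code -> base

    def __post_init__(self) -> None:
        if sorted(self.encode) != list(_CODES) or sorted(self.encode.values()) != list("ACGT"):
            raise ValueError("code table must be a bijection {00,01,10,11} -> {A,C,G,T}")
        if not self.is_complement_consistent(self.encode):
            raise ValueError(f"table {self.id} is not complement-consistent")
        object.__setattr__(self, "encode", MappingProxyType(dict(self.encode)))

    @property
    def decode(self) -> dict[str, str]:
        """base -> 2-bit code."""
        return {b: c for c, b in self.encode.items()}

    @staticmethod
    def is_complement_consistent(encode: Mapping[str, str]) -> bool:
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        notbits = {"0": "1", "1": "0"}
        decode = {b: c for c, b in encode.items()}
        return all(
            decode[comp[b]] == "".join(notbits[x] for x in c)
            for c, b in encode.items()
        )


# The 8 admissible tables, in their conventional published order.
_TABLE_ROWS: dict[int, str] = {
    1: "ACGT",
    2: "AGCT",
    3: "CATG",
    4: "CTAG",
    5: "GATC",
    6: "GTAC",
    7: "TCGA",
    8: "TGCA",
}

_TABLES: dict[int, CodeTable] = {
    tid: CodeTable(tid, dict(zip(_CODES, bases))) for tid, bases in _TABLE_ROWS.items()
}


def list_code_tables() -> list[CodeTable]:
    """All 8 complement-consistent code tables, ids 1-8."""
    return [_TABLES[i] for i in sorted(_TABLES)]


def get_code_table(table_id: int) -> CodeTable:
    try:
        return _TABLES[table_id]
    except KeyError:
        raise KeyError(f"no code table {table_id}; valid ids are 1-8") from None


def text_to_bits(text: str) -> str:
    """ASCII text -> bit string, 8 bits per character, MSB first."""
    out = []
    for ch in text:
        code = ord(ch)
        if code > 127:
            raise ValueError(f"non-ASCII character {ch!r} (codepoint {code})")
        out.append(format(code, "08b"))
    return "".join(out)


def bits_to_text(bits: str) -> str:
    """Inverse of :func:`text_to_bits`; requires a multiple of 8 bits."""
    _check_bits(bits)
    if len(bits) % 8:
        raise ValueError(f"bit length {len(bits)} is not a multiple of 8")
    return "".join(chr(int(bits[i : i + 8], 2)) for i in range(0, len(bits), 8))


def bits_to_dna(bits: str, table: CodeTable) -> DnaSequence:
    """Map each 2-bit code to its base under *table*; bit length must be even."""
    _check_bits(bits)
    if len(bits) % 2:
        raise ValueError(f"bit length {len(bits)} is odd; 2 bits encode one base")
    enc = table.encode
    return DnaSequence("".join(enc[bits[i : i + 2]] for i in range(0, len(bits), 2)))


def dna_to_bits(seq: str, table: CodeTable) -> str:
    """Inverse of :func:`bits_to_dna`."""
    dec = table.decode
    return "".join(dec[b] for b in DnaSequence(seq))


def _check_bits(bits: str) -> None:
    bad = set(bits) - {"0", "1"}
    if bad:
        raise ValueError(f"bit strings contain only 0/1, got {sorted(bad)!r}")
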