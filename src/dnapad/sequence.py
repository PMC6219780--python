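"""Validated DNA sequence primitive.

Every strand in the system — reference strands, pyramid edges and faces,
stego carriers, primers — is a :class:`DnaSequence`: an immutable string
over the strict alphabet {A, C, G, T} with Watson–Crick complement
semantics.  Lowercase input is normalised to uppercase; any other residue
is rejected at construction time so downstream code never has to re-check.
"""

from __future__ import annotations

__all__ = ["DnaSequence", "complement", "revcomp", "random_dna"]

_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class DnaSequence(str):
    """An A/C/G/T string.  ``revcomp(revcomp(s)) == s`` by construction."""

    __slots__ = ()

    def __new__(cls, residues: str) -> "DnaSequence":
        s = str(residues).upper()
        bad = set(s) - _ALPHABET
        if bad:
            raise ValueError(
                f"invalid residue(s) {sorted(bad)!r}: DNA sequences are A/C/G/T only"
            )
        return super().__new__(cls, s)

    def complement(self) -> "DnaSequence":
        """Base-wise Watson–Crick complement (A<->T, C<->G), same orientation."""
        return DnaSequence(self.translate(_COMPLEMENT))

    def revcomp(self) -> "DnaSequence":
        """Reverse complement: the sequence of the antiparallel partner strand."""
        return DnaSequence(self.translate(_COMPLEMENT)[::-1])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DnaSequence({str.__repr__(self)})"


def complement(seq: str) -> DnaSequence:
    return DnaSequence(seq).complement()


def revcomp(seq: str) -> DnaSequence:
    return DnaSequence(seq).revcomp()


def random_dna(length: int, rng) -> DnaSequence:
    """Uniform-composition random sequence from a numpy Generator."""
    if length < 0:
        raise ValueError("length must be non-negative")
    bases = rng.choice(list("ACGT"), size=length)
    return DnaSequence("".join(bases))
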