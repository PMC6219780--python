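"""Steganographic transport of the interception offsets.

The four secret offsets r1..r4 never travel in the clear: each is written
as a fixed-width binary integer, mapped to DNA under the secret code
table, and the four payloads are framed between the secret primer q and
its closing primer q' (reverse complement of q), followed by a random
redundancy tail s5:

    carrier = q  s1 s2 s3 s4  q'  s5

The carrier is published in a pool of decoy strands; only a holder of q
(and the code table) can locate and decode it.  The payload width is
fixed (default 16 bits -> 8 nt per offset) so parsing needs no
separators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly import OffsetSet, SEGMENT_LEN
from .codec import CodeTable, bits_to_dna, dna_to_bits
from .sequence import DnaSequence, random_dna

__all__ = ["StegoCarrier", "hide_offsets", "extract_offsets", "DEFAULT_OFFSET_BITS"]

DEFAULT_OFFSET_BITS = 16  # capacity 65535 >= L-16 for kilobase references


@dataclass(frozen=True)
class StegoCarrier:
    """The framed carrier strand and its parts."""

    q: DnaSequence
    payloads: tuple[DnaSequence, DnaSequence, DnaSequence, DnaSequence]
    q_prime: DnaSequence
    s5: DnaSequence

    @property
    def full(self) -> DnaSequence:
        return DnaSequence(
            self.q + "".join(self.payloads) + self.q_prime + self.s5
        )


def hide_offsets(
    offsets: OffsetSet,
    table: CodeTable,
    q: DnaSequence,
    redundancy_len: int = 20,
    seed: int = 0,
    width_bits: int = DEFAULT_OFFSET_BITS,
) -> StegoCarrier:
    """Encode the four offsets into a primer-flanked carrier."""
    q = DnaSequence(q)
    if not q:
        raise ValueError("primer q must be non-empty")
    if width_bits % 2:
        raise ValueError("width_bits must be even (2 bits per base)")
    cap = 2**width_bits - 1
    payloads = []
    for ri in offsets.r:
        if ri > cap:
            raise ValueError(f"offset {ri} exceeds {width_bits}-bit capacity {cap}")
        payloads.append(bits_to_dna(format(ri, f"0{width_bits}b"), table))
    rng = np.random.default_rng(seed)
    # s5 is noise; reject draws containing q so the primer anchor stays unique.
    while True:
        s5 = random_dna(redundancy_len, rng)
        if q not in s5:
            break
    return StegoCarrier(q, tuple(payloads), q.revcomp(), s5)


def extract_offsets(
    pool: list[DnaSequence] | list[str],
    table: CodeTable,
    q: DnaSequence,
    L: int,
    p_id: str = "p",
    width_bits: int = DEFAULT_OFFSET_BITS,
) -> OffsetSet:
    """Locate the carrier in a decoy pool by its primer and decode the offsets.

    Exactly one pool strand may start with q.  The closing primer q' is
    verified before decoding; a mismatch means the carrier was corrupted
    in transit.  Decoded offsets outside [1, L-16] are rejected.
    """
    q = DnaSequence(q)
    matches = [DnaSequence(s) for s in pool if DnaSequence(s).startswith(q)]
    if not matches:
        raise LookupError(f"no strand in the pool starts with primer {q}")
    if len(matches) > 1:
        raise LookupError(f"{len(matches)} strands start with the primer; carrier ambiguous")
    carrier = matches[0]
    width_nt = width_bits // 2
    body_start = len(q)
    qp_start = body_start + 4 * width_nt
    qp_end = qp_start + len(q)
    if len(carrier) < qp_end:
        raise ValueError("carrier too short for four payloads and a closing primer")
    if carrier[qp_start:qp_end] != q.revcomp():
        raise ValueError("closing primer q' mismatch: carrier corrupted")
    r = []
    for i in range(4):
        s_i = carrier[body_start + i * width_nt : body_start + (i + 1) * width_nt]
        r.append(int(dna_to_bits(s_i, table), 2))
    hi = L - SEGMENT_LEN
    for ri in r:
        if not 1 <= ri <= hi:
            raise ValueError(f"decoded offset {ri} outside [1, {hi}]: carrier corrupted")
    return OffsetSet(p_id=p_id, L=L, r=tuple(r))
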