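"""End-to-end one-time-pad encryption and decryption pipelines.

Two schemes share the same machinery.  The *single-bit* scheme XORs each
plaintext bit with one key bit through the pyramid calculator: strand A'
carries a 1, strand B' a 0, and the monochrome fluorescence readout is
the cipher bit.  The *double-bit* scheme processes bit pairs: the four
strands A'..D' carry the codes 00..11 and the three-colour readout
(colourless/red/green/blue) is the cipher pair.

A message is encrypted as follows: a reference strand p is drawn from
the strand database; four secret offsets select the 16-nt segments
M1..M4 that define this message's pyramid; the offsets are hidden in a
primer-flanked stego carrier (the public r*); the key bits come from the
logistic map seeded by the shared (g, mu); each bit (or pair) is then
put through the simulated displacement reaction.  Decryption recovers
the offsets from the carrier pool, rebuilds the same pyramid, regenerates
the key, and runs the inverse XOR through the same calculator.

The shared secret is (g, mu, code table R, reference id p, primer q);
the key k is derived, never transmitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .assembly import (
    ReferenceDatabase,
    build_pyramid,
    draw_offsets,
    intercept_segments,
    select_reference,
)
from .codec import bits_to_text, get_code_table, text_to_bits
from .displacement import COLOR_TO_CODE, double_bit_xor, gate
from .keystream import KeystreamParams, keystream_bits
from .sequence import DnaSequence
from .stego import StegoCarrier, extract_offsets, hide_offsets

__all__ = ["SecretKeySet", "Seeds", "CipherRecord", "encrypt", "decrypt"]

logger = logging.getLogger(__name__)

# One-time discipline: a (structure, key) pair must never encrypt twice.
_used_pads: set[tuple] = set()

_COLOR_SYMBOL = {"colorless": "N", "red": "R", "green": "G", "blue": "B"}
_SYMBOL_COLOR = {v: k for k, v in _COLOR_SYMBOL.items()}


@dataclass
class SecretKeySet:
    """The confidential parameter set (g, mu, R, p, q).

    ``p_id`` may be left None; encryption then selects the reference
    strand itself (seeded) and records the choice here.
    """

    g: float
    mu: float
    table_id: int
    q: DnaSequence
    p_id: str | None = None
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.q = DnaSequence(self.q)
        get_code_table(self.table_id)  # validate id early
        KeystreamParams(self.g, self.mu, self.threshold)


@dataclass(frozen=True)
class Seeds:
    """Independent seeds for each stochastic pipeline stage."""

    selection: int = 0
    offsets: int = 1
    sides: int = 2
    s5: int = 3

    @classmethod
    def from_root(cls, root: int) -> "Seeds":
        children = np.random.SeedSequence(root).spawn(4)
        return cls(*(int(c.generate_state(1)[0] % 2**31) for c in children))


@dataclass(frozen=True)
class CipherRecord:
    """The public ciphertext bundle: fluorescence spectrum + stego carrier.

    ``spectrum`` is one symbol per operation: '0'/'1' for the single-bit
    scheme, 'N'/'R'/'G'/'B' (colourless/red/green/blue) for double-bit.
    ``manifest`` carries the public structure parameters.
    """

    scheme: str
    spectrum: str
    carrier: StegoCarrier
    manifest: dict = field(default_factory=dict)

    def spectrum_lines(self) -> str:
        """Serialise as the one-symbol-per-line spectrum file dialect."""
        return "\n".join([f"# scheme: {self.scheme}", *self.spectrum]) + "\n"


def _prepare(secrets: SecretKeySet, db: ReferenceDatabase, seeds: Seeds):
    """Shared front half of both schemes: structure + carrier."""
    if secrets.p_id is None:
        secrets.p_id, _ = select_reference(db, seeds.selection)
    p = db.get(secrets.p_id)
    offsets = draw_offsets(len(p), seeds.offsets, p, p_id=secrets.p_id)
    table = get_code_table(secrets.table_id)
    carrier = hide_offsets(offsets, table, secrets.q, seed=seeds.s5)
    M = intercept_segments(p, offsets)
    structure = build_pyramid(M, seed=seeds.sides)

    pad_key = (secrets.g, secrets.mu, secrets.p_id, offsets.r)
    if pad_key in _used_pads:
        logger.warning(
            "one-time-pad reuse: structure %s with key (g=%r, mu=%r) has already "
            "encrypted a message",
            offsets.r,
            secrets.g,
            secrets.mu,
        )
    _used_pads.add(pad_key)
    return offsets, carrier, structure


def _rebuild(secrets: SecretKeySet, db: ReferenceDatabase, pool) -> "PyramidStructure":
    """Decryption front half: recover offsets from the pool, rebuild the pyramid."""
    if secrets.p_id is None:
        raise ValueError("decryption requires the shared reference id p")
    p = db.get(secrets.p_id)
    table = get_code_table(secrets.table_id)
    offsets = extract_offsets(pool, table, secrets.q, L=len(p), p_id=secrets.p_id)
    M = intercept_segments(p, offsets)
    return build_pyramid(M, seed=0)


def _key(secrets: SecretKeySet, nbits: int) -> str:
    return keystream_bits(
        KeystreamParams(secrets.g, secrets.mu, secrets.threshold), nbits
    )


def encrypt(
    plaintext: str,
    secrets: SecretKeySet,
    db: ReferenceDatabase,
    seeds: Seeds,
    scheme: str = "single",
) -> CipherRecord:
    """Encrypt ASCII plaintext; the key length always equals the bit length."""
    if scheme not in ("single", "double"):
        raise ValueError(f"unknown scheme {scheme!r}")
    bits = text_to_bits(plaintext)
    offsets, carrier, structure = _prepare(secrets, db, seeds)
    k = _key(secrets, len(bits))

    if scheme == "single":
        spectrum = "".join(
            str(gate("XOR", [int(m), int(kb)], structure)) for m, kb in zip(bits, k)
        )
    else:
        symbols = []
        for i in range(0, len(bits), 2):
            readout = double_bit_xor(bits[i : i + 2], k[i : i + 2], structure)
            symbols.append(_COLOR_SYMBOL[readout.signal])
        spectrum = "".join(symbols)

    manifest = {
        "scheme": scheme,
        "n_bits": len(bits),
        **{
            key: val
            for key, val in structure.manifest().items()
            if key in ("RS1", "RS2", "toeholds")
        },
    }
    return CipherRecord(scheme=scheme, spectrum=spectrum, carrier=carrier, manifest=manifest)


def decrypt(
    record: CipherRecord,
    secrets: SecretKeySet,
    db: ReferenceDatabase,
    pool=None,
) -> str:
    """Decrypt a cipher record; ``pool`` defaults to just the record's carrier."""
    if pool is None:
        pool = [record.carrier.full]
    structure = _rebuild(secrets, db, pool)

    if record.scheme == "single":
        nbits = len(record.spectrum)
        if nbits % 8:
            raise ValueError(f"spectrum length {nbits} is not a multiple of 8 bits")
        k = _key(secrets, nbits)
        bits = "".join(
            str(gate("XOR", [int(c), int(kb)], structure))
            for c, kb in zip(record.spectrum, k)
        )
    elif record.scheme == "double":
        nbits = 2 * len(record.spectrum)
        if nbits % 8:
            raise ValueError(f"spectrum decodes to {nbits} bits, not a multiple of 8")
        k = _key(secrets, nbits)
        parts = []
        for i, sym in enumerate(record.spectrum):
            try:
                cipher_code = COLOR_TO_CODE[_SYMBOL_COLOR[sym]]
            except KeyError:
                raise ValueError(f"invalid spectrum symbol {sym!r}") from None
            readout = double_bit_xor(cipher_code, k[2 * i : 2 * i + 2], structure)
            parts.append(readout.code)
        bits = "".join(parts)
    else:
        raise ValueError(f"unknown scheme {record.scheme!r}")
    return bits_to_text(bits)
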