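"""Construction of the pyramid "calculator" nanostructure.

The calculator is a pentahedral DNA self-assembly: a square base whose
four 42-nt edges each read RS1–M_i–RS2 (8 + 16 + 18 nt), closed by four
lateral triangular faces A, B, C, D in cyclic order.  Each face carries a
base strand that is the exact reverse complement of its edge, preceded by
a unique single-stranded toehold that nucleates strand displacement; the
two slanted sides of adjacent faces are mutually complementary, which is
what holds the pyramid closed.

The secret of a given structure is the four 16-nt segments M1..M4,
intercepted from a reference strand p (drawn from a strand database) at
four secret offsets r1..r4 in the 1-based interval [1, L-16].  RS1, RS2
and the four toeholds are public, fixed sequences.

This module builds and validates structures and provides the synthetic
reference-strand database generator used in place of a public sequence
repository.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as _io
from .sequence import DnaSequence, random_dna

__all__ = [
    "RS1_DEFAULT",
    "RS2_DEFAULT",
    "TOEHOLDS_DEFAULT",
    "FACE_LABELS",
    "ReferenceDatabase",
    "OffsetSet",
    "Face",
    "PyramidStructure",
    "ValidationReport",
    "generate_database",
    "select_reference",
    "draw_offsets",
    "intercept_segments",
    "build_pyramid",
    "validate_pyramid",
]

SEGMENT_LEN = 16  # each secret M_i
RS1_LEN, RS2_LEN = 8, 18
EDGE_LEN = RS1_LEN + SEGMENT_LEN + RS2_LEN  # 42 nt

FACE_LABELS = ("A", "B", "C", "D")

# Package-default public sequences.  The scheme treats RS1-RS2 and the
# toeholds as open, reusable sequences; these defaults are fixed here so
# that structures are reproducible, and are overridable per call.
RS1_DEFAULT = DnaSequence("ATCGGCTA")
RS2_DEFAULT = DnaSequence("TGCACGTTAGGATCAATC")
TOEHOLDS_DEFAULT = (
    DnaSequence("ACCTTG"),
    DnaSequence("GTTGAC"),
    DnaSequence("CAAGGA"),
    DnaSequence("TGGTCA"),
)


@dataclass(frozen=True)
class ReferenceDatabase:
    """Pool of candidate reference strands; ``lam`` is the strand count λ."""

    strands: tuple[tuple[str, DnaSequence], ...]

    def __post_init__(self) -> None:
        ids = [sid for sid, _ in self.strands]
        if len(set(ids)) != len(ids):
            raise ValueError("strand ids must be unique")
        for sid, seq in self.strands:
            if len(seq) < SEGMENT_LEN + 1:
                raise ValueError(
                    f"strand {sid!r} has length {len(seq)} < {SEGMENT_LEN + 1}; "
                    "the offset interval [1, L-16] would be empty"
                )

    @property
    def lam(self) -> int:
        return len(self.strands)

    def get(self, strand_id: str) -> DnaSequence:
        for sid, seq in self.strands:
            if sid == strand_id:
                return seq
        raise KeyError(f"no strand {strand_id!r} in database")

    def to_fasta(self, path: str | Path) -> None:
        _io.write_fasta(self.strands, path)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceDatabase":
        return cls(tuple(_io.read_fasta(path)))


@dataclass(frozen=True)
class OffsetSet:
    """Four secret interception offsets into reference strand ``p_id``.

    Offsets are 1-based and inclusive, each in [1, L-16]; offset r yields
    the 16-mer at positions r .. r+15.
    """

    p_id: str
    L: int
    r: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.r) != 4:
            raise ValueError("exactly four offsets required")
        if len(set(self.r)) != 4:
            raise ValueError(f"offsets must be pairwise distinct, got {self.r}")
        hi = self.L - SEGMENT_LEN
        for ri in self.r:
            if not 1 <= ri <= hi:
                raise ValueError(f"offset {ri} outside [1, {hi}]")


@dataclass(frozen=True)
class Face:
    """One lateral triangle: toehold + base strand + two slanted sides.

    ``base`` is the full base strand: the toehold followed by the reverse
    complement of the corresponding square edge.  ``side_prev`` pairs with
    the previous face in cyclic order, ``side_next`` with the next.
    """

    label: str
    toehold: DnaSequence
    base: DnaSequence
    side_prev: DnaSequence
    side_next: DnaSequence

    @property
    def base_pairing_region(self) -> DnaSequence:
        """Base strand minus the toehold: the part hybridised to the edge."""
        return DnaSequence(self.base[len(self.toehold):])


@dataclass(frozen=True)
class PyramidStructure:
    RS1: DnaSequence
    RS2: DnaSequence
    M: tuple[DnaSequence, DnaSequence, DnaSequence, DnaSequence]
    toeholds: tuple[DnaSequence, DnaSequence, DnaSequence, DnaSequence]
    edges: tuple[DnaSequence, DnaSequence, DnaSequence, DnaSequence]
    faces: tuple[Face, Face, Face, Face]

    def face(self, label: str) -> Face:
        try:
            return self.faces[FACE_LABELS.index(label)]
        except ValueError:
            raise KeyError(f"no face {label!r}; faces are {FACE_LABELS}") from None

    def input_strand(self, label: str) -> DnaSequence:
        """The invader strand X' fully complementary to face X."""
        f = self.face(label)
        return DnaSequence(f.side_prev + f.base + f.side_next).revcomp()

    def manifest(self) -> dict:
        """Public structure description (sequences of every component)."""
        return {
            "RS1": str(self.RS1),
            "RS2": str(self.RS2),
            "toeholds": [str(t) for t in self.toeholds],
            "edges": {lab: str(e) for lab, e in zip("abcd", self.edges)},
            "faces": {
                f.label: {
                    "toehold": str(f.toehold),
                    "base": str(f.base),
                    "side_prev": str(f.side_prev),
                    "side_next": str(f.side_next),
                }
                for f in self.faces
            },
        }

    def export_fasta(self, path: str | Path) -> None:
        records = [(f"edge_{lab}", e) for lab, e in zip("abcd", self.edges)]
        for f in self.faces:
            records.append((f"face_{f.label}_base", f.base))
            records.append((f"face_{f.label}_side_prev", f.side_prev))
            records.append((f"face_{f.label}_side_next", f.side_next))
        records.extend((f"toehold_T{i+1}", t) for i, t in enumerate(self.toeholds))
        _io.write_fasta(records, path)


def generate_database(count: int, length: int, seed: int) -> ReferenceDatabase:
    """Seeded synthetic reference-strand database (uniform base composition).

    Stands in for a public sequence repository; strands are named
    ``ref_0001`` onward.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if length < SEGMENT_LEN + 1:
        raise ValueError(f"length must be >= {SEGMENT_LEN + 1}")
    rng = np.random.default_rng(seed)
    strands = tuple(
        (f"ref_{i + 1:04d}", random_dna(length, rng)) for i in range(count)
    )
    return ReferenceDatabase(strands)


def select_reference(db: ReferenceDatabase, seed: int) -> tuple[str, int]:
    """Uniformly select the reference strand; returns (id, length)."""
    if db.lam == 0:
        raise ValueError("database is empty")
    rng = np.random.default_rng(seed)
    idx = int(rng.integers(1, db.lam + 1))  # 1-based index x in [1, lambda]
    sid, seq = db.strands[idx - 1]
    return sid, len(seq)


def draw_offsets(
    L: int,
    seed: int,
    p: DnaSequence,
    p_id: str = "p",
    max_attempts: int = 1000,
) -> OffsetSet:
    """Draw four distinct offsets in [1, L-16] whose 16-mers are distinct.

    Offsets are redrawn (up to *max_attempts*) until the four intercepted
    segments are pairwise distinct as sequences; a degenerate reference
    (e.g. a homopolymer) makes this impossible and raises.
    """
    if len(p) != L:
        raise ValueError(f"reference length {len(p)} does not match L={L}")
    hi = L - SEGMENT_LEN
    if hi < 1:
        raise ValueError(f"L must be >= {SEGMENT_LEN + 1}, got {L}")
    if hi < 4:
        raise ValueError(
            f"interval [1, {hi}] holds fewer than four distinct offsets (L={L})"
        )
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        r = tuple(int(x) for x in rng.choice(hi, size=4, replace=False) + 1)
        segments = {str(p[ri - 1 : ri - 1 + SEGMENT_LEN]) for ri in r}
        if len(segments) == 4:
            return OffsetSet(p_id=p_id, L=L, r=r)
    raise RuntimeError(
        f"no quadruple of distinct 16-mers found in {max_attempts} attempts; "
        "the reference strand is too repetitive"
    )


def intercept_segments(p: DnaSequence, offsets: OffsetSet) -> tuple[DnaSequence, ...]:
    """Cut the four 16-nt segments M1..M4 at the 1-based offsets."""
    if len(p) != offsets.L:
        raise ValueError("reference strand length does not match offset set")
    out = []
    for ri in offsets.r:
        seg = p[ri - 1 : ri - 1 + SEGMENT_LEN]
        if len(seg) != SEGMENT_LEN:
            raise ValueError(f"offset {ri} runs past the end of the strand")
        out.append(DnaSequence(seg))
    return tuple(out)


def build_pyramid(
    M: tuple[DnaSequence, DnaSequence, DnaSequence, DnaSequence],
    RS1: DnaSequence = RS1_DEFAULT,
    RS2: DnaSequence = RS2_DEFAULT,
    toeholds: tuple[DnaSequence, ...] = TOEHOLDS_DEFAULT,
    side_length: int = 16,
    seed: int = 0,
) -> PyramidStructure:
    """Assemble the pyramid from its components.

    Edges are RS1+M_i+RS2; each face base is its toehold followed by the
    reverse complement of its edge; slanted sides are generated (seeded)
    so that adjacent faces carry mutually complementary side domains.
    """
    RS1, RS2 = DnaSequence(RS1), DnaSequence(RS2)
    M = tuple(DnaSequence(m) for m in M)
    toeholds = tuple(DnaSequence(t) for t in toeholds)
    if len(RS1) != RS1_LEN:
        raise ValueError(f"RS1 must be {RS1_LEN} nt, got {len(RS1)}")
    if len(RS2) != RS2_LEN:
        raise ValueError(f"RS2 must be {RS2_LEN} nt, got {len(RS2)}")
    if len(M) != 4 or any(len(m) != SEGMENT_LEN for m in M):
        raise ValueError(f"four M segments of {SEGMENT_LEN} nt required")
    if len(set(M)) != 4:
        raise ValueError("M segments must have distinct sequences")
    if len(toeholds) != 4 or len(set(toeholds)) != 4:
        raise ValueError("four distinct toeholds required")

    edges = tuple(DnaSequence(RS1 + m + RS2) for m in M)

    # One shared side domain per adjacent pair, in cyclic order
    # (A,B), (B,C), (C,D), (D,A); the following face carries its revcomp.
    rng = np.random.default_rng(seed)
    shared = [random_dna(side_length, rng) for _ in range(4)]
    faces = []
    for i, lab in enumerate(FACE_LABELS):
        base = DnaSequence(toeholds[i] + edges[i].revcomp())
        side_next = shared[i]
        side_prev = shared[(i - 1) % 4].revcomp()
        faces.append(Face(lab, toeholds[i], base, side_prev, side_next))
    return PyramidStructure(RS1, RS2, M, toeholds, edges, tuple(faces))


@dataclass
class ValidationReport:
    """Per-invariant pass/fail record; never raises."""

    checks: list[tuple[str, bool, str]] = field(default_factory=list)

    def add(self, name: str, ok: bool, detail: str = "") -> None:
        self.checks.append((name, ok, detail))

    @property
    def passed(self) -> bool:
        return all(ok for _, ok, _ in self.checks)

    def failures(self) -> list[tuple[str, str]]:
        return [(name, detail) for name, ok, detail in self.checks if not ok]


def validate_pyramid(s: PyramidStructure) -> ValidationReport:
    """Check every geometric and complementarity invariant of the structure."""
    rep = ValidationReport()
    rep.add("RS1 length", len(s.RS1) == RS1_LEN, f"got {len(s.RS1)}, want {RS1_LEN}")
    rep.add("RS2 length", len(s.RS2) == RS2_LEN, f"got {len(s.RS2)}, want {RS2_LEN}")
    for i, m in enumerate(s.M, 1):
        rep.add(f"M{i} length", len(m) == SEGMENT_LEN, f"got {len(m)}, want {SEGMENT_LEN}")
    rep.add("M distinct", len(set(s.M)) == 4, "duplicate M segments")
    for lab, edge, m in zip("abcd", s.edges, s.M):
        rep.add(f"edge {lab} length", len(edge) == EDGE_LEN, f"got {len(edge)}")
        rep.add(
            f"edge {lab} composition",
            edge == s.RS1 + m + s.RS2,
            "edge is not RS1+M+RS2",
        )
    rep.add(
        "toeholds distinct", len(set(s.toeholds)) == 4, "duplicate toeholds"
    )
    rep.add(
        "toeholds disjoint from RS1/RS2",
        all(t not in s.RS1 and t not in s.RS2 for t in s.toeholds),
        "a toehold occurs inside RS1 or RS2",
    )
    for i, (f, edge) in enumerate(zip(s.faces, s.edges)):
        rep.add(
            f"face {f.label} complementarity",
            f.base_pairing_region == edge.revcomp(),
            "base strand (minus toehold) is not the reverse complement of its edge",
        )
        nxt = s.faces[(i + 1) % 4]
        rep.add(
            f"sides {f.label}-{nxt.label} complementary",
            f.side_next == nxt.side_prev.revcomp(),
            "adjacent side domains are not complementary",
        )
    return rep
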