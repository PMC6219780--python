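"""Rule-based simulator of toehold-mediated strand displacement on the pyramid.

The model is at domain level, not kinetic: an input strand X' is fully
complementary to face X, so adding it always displaces that face (the
toehold hybridisation that nucleates the reaction is a precondition
automatically met by a full-complement invader).  What the fluorescence
detector can see is governed purely by geometry:

* the RS1-RS2 joint at a base corner is exposed iff *both* faces meeting
  at that corner have been displaced (corners AB, BC, CD, DA in cyclic
  order);
* the monochrome detector — a reporter duplex of RS2 against RS1*-RS2* —
  lights up iff at least one joint is exposed;
* the two-bit calculator uses three coloured detectors: red for the
  corner class {AB, CD}, blue for {DA, BC}, and green for the
  relative-pair (diagonal) displacement {A,C} or {B,D}; equal inputs add
  no detector and read colourless.

Displacement is monotone (a displaced face stays displaced) and adding a
strand twice equals adding it once.  Each gate evaluation runs on a fresh
state, so successive bit operations never interfere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .assembly import FACE_LABELS, PyramidStructure, build_pyramid
from .sequence import DnaSequence

__all__ = [
    "DisplacementState",
    "Readout",
    "fresh_state",
    "add_inputs",
    "add_detector",
    "exposed_joints",
    "read_mono",
    "gate",
    "double_bit_xor",
    "demo_structure",
    "CODE_TO_STRAND",
    "COLOR_TO_CODE",
]

CORNERS = ("AB", "BC", "CD", "DA")
DETECTORS = ("mono", "red_a", "green_b", "blue_c")

# Two-bit codes carried by the four input strands, and the colour that
# decodes each ciphertext code.
CODE_TO_STRAND = {"00": "A'", "01": "B'", "10": "C'", "11": "D'"}
STRAND_TO_CODE = {v: k for k, v in CODE_TO_STRAND.items()}
COLOR_TO_CODE = {"colorless": "00", "red": "01", "green": "10", "blue": "11"}

# Corner classes reported by the red vs blue detectors.
_RED_CORNERS = frozenset({"AB", "CD"})
_BLUE_CORNERS = frozenset({"BC", "DA"})


def _face_of(strand: str) -> str:
    lab = strand.rstrip("'′")
    if lab not in FACE_LABELS:
        raise KeyError(f"unknown input strand {strand!r}; expected A'...D'")
    return lab


@dataclass(frozen=True)
class DisplacementState:
    """Immutable snapshot of the reaction medium."""

    structure: PyramidStructure
    displaced: frozenset[str] = frozenset()
    detectors: frozenset[str] = frozenset()
    trace: tuple[str, ...] = ()


@dataclass(frozen=True)
class Readout:
    """Detector signal and the 1- or 2-bit value it decodes to."""

    signal: str  # '0'/'1' for mono, or a colour name
    code: str


def fresh_state(structure: PyramidStructure) -> DisplacementState:
    return DisplacementState(structure=structure)


def add_inputs(state: DisplacementState, strands) -> DisplacementState:
    """Add invader strands; their faces are displaced (idempotently)."""
    faces = frozenset(_face_of(s) for s in strands)
    return replace(
        state,
        displaced=state.displaced | faces,
        trace=state.trace
        + (f"add {sorted(strands)} -> displaced {sorted(state.displaced | faces)}",),
    )


def add_detector(state: DisplacementState, detector: str) -> DisplacementState:
    if detector not in DETECTORS:
        raise KeyError(f"unknown detector {detector!r}; valid: {DETECTORS}")
    return replace(
        state,
        detectors=state.detectors | {detector},
        trace=state.trace + (f"add detector {detector}",),
    )


def exposed_joints(state: DisplacementState) -> frozenset[str]:
    """Corners whose RS1-RS2 joint is exposed: both flanking faces displaced."""
    d = state.displaced
    return frozenset(c for c in CORNERS if c[0] in d and c[1] in d)


def read_mono(state: DisplacementState) -> Readout:
    """Monochrome fluorescence: 1 iff any joint is exposed.

    The detector must have been added first; reading without one is a
    protocol error, not a 0.
    """
    if "mono" not in state.detectors:
        raise RuntimeError("mono detector not added; readout undefined")
    bit = "1" if exposed_joints(state) else "0"
    return Readout(signal=bit, code=bit)


def demo_structure(seed: int = 0) -> PyramidStructure:
    """A fixed valid structure for gate evaluation outside a cipher run."""
    M = (
        DnaSequence("ACGTACGTACGTACGT"),
        DnaSequence("TTGACCATGGATCCAA"),
        DnaSequence("GGCATTCAGTCAAGGT"),
        DnaSequence("CATGCCTTAACGGATC"),
    )
    return build_pyramid(M, seed=seed)


def gate(kind: str, inputs, structure: PyramidStructure | None = None) -> int:
    """Evaluate one logic gate on a fresh structure.

    Input encoding: for XOR, NOT and OR an operand 1 adds strand A' and an
    operand 0 adds strand B'; NOT pre-displaces face C and OR pre-displaces
    face D.  For AND, an operand 1 adds that operand's own strand (A' for
    the first, B' for the second) and 0 adds nothing.  The readout is the
    monochrome detector.
    """
    kind = kind.upper()
    inputs = [int(b) for b in inputs]
    if any(b not in (0, 1) for b in inputs):
        raise ValueError(f"inputs must be bits, got {inputs}")
    arity = 1 if kind == "NOT" else 2
    if len(inputs) != arity:
        raise ValueError(f"{kind} takes {arity} input(s), got {len(inputs)}")

    state = fresh_state(structure if structure is not None else demo_structure())
    if kind == "NOT":
        state = add_inputs(state, ["C'"])
    elif kind == "OR":
        state = add_inputs(state, ["D'"])
    elif kind not in ("XOR", "AND"):
        raise ValueError(f"unknown gate kind {kind!r}")

    if kind == "AND":
        operand_strands = ("A'", "B'")
        to_add = [s for s, b in zip(operand_strands, inputs) if b]
    else:
        to_add = ["A'" if b else "B'" for b in inputs]
    if to_add:
        state = add_inputs(state, to_add)
    state = add_detector(state, "mono")
    return int(read_mono(state).code)


def double_bit_xor(
    x: str, y: str, structure: PyramidStructure | None = None
) -> Readout:
    """Two-bit XOR via the three-colour calculator.

    x and y are 2-bit codes; each is carried by its strand (00->A',
    01->B', 10->C', 11->D').  Equal strands add no detector (colourless,
    00); a diagonal pair adds the green detector (10); an adjacent pair
    adds the red and blue detectors and the exposed corner's class decides
    which hybridises (red 01, blue 11).  The decoded code always equals
    the bitwise XOR of x and y.
    """
    for v in (x, y):
        if v not in CODE_TO_STRAND:
            raise ValueError(f"invalid 2-bit code {v!r}")
    state = fresh_state(structure if structure is not None else demo_structure())
    state = add_inputs(state, [CODE_TO_STRAND[x], CODE_TO_STRAND[y]])

    if x == y:
        # same strand twice: one face displaced, nothing to report
        color = "colorless"
    else:
        joints = exposed_joints(state)
        if not joints:
            # diagonal (relative) pair: the green detector reports it
            state = add_detector(state, "green_b")
            color = "green"
        else:
            state = add_detector(state, "red_a")
            state = add_detector(state, "blue_c")
            (corner,) = joints
            color = "red" if corner in _RED_CORNERS else "blue"
    return Readout(signal=color, code=COLOR_TO_CODE[color])
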