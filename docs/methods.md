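# Methods

## What is modelled, and at what level

The package simulates a DNA one-time-pad cryptosystem at the *rule* level:
sequences are explicit and every informational invariant (complementarity,
lengths, framing) is enforced, but reactions are not kinetic. Toehold
binding is treated as a precondition automatically satisfied by a
full-complement invader, displacement is instantaneous and complete, and
"fluorescence" is a binary (or four-colour) abstraction of what a real
spectrum would show. No rate constants, concentrations, melting
temperatures or leak reactions are modelled — the sources for this class
of scheme specify none — so passing tests demonstrate the *logical*
correctness of the cryptosystem, not wet-lab feasibility.

## The calculator

Geometry is fixed: RS1 = 8 nt, RS2 = 18 nt, each secret segment Mᵢ = 16 nt,
every edge RS1+Mᵢ+RS2 = 42 nt. Corner joints sit between cyclically
adjacent faces (AB, BC, CD, DA); a joint is exposed iff both flanking
faces are displaced; the monochrome reporter reads 1 iff at least one
joint is exposed. Displacement state is monotone (a displaced face stays
displaced) and set-valued (adding a strand twice equals adding it once),
which is what makes `1 ⊕ 1` read 0: the same invader twice displaces one
face and exposes nothing.

Three rules are protocol conventions rather than sequence-derivable
mechanics, and are implemented as such:

- **Red/blue corner classes.** Adjacent displacements {A,B} or {C,D} read
  red (code 01); {B,C} or {D,A} read blue (code 11). The sequence-level
  mechanism that would distinguish the two corner classes is not specified
  by the scheme; the assignment is a fixed rule here.
- **Green on diagonal pairs.** Displacing a diagonal pair ({A,C} or
  {B,D}) exposes no joint, yet reads green (code 10) through its own
  detector. There is no plausible joint-based mechanism for this; it is
  flagged as biologically unexplained and modelled as a rule.
- **Detectors are added after displacement**, per protocol; reading
  without a detector is an error, not a 0, so protocol mistakes surface
  instead of silently reading as signal-absent.

Evaluating a gate never mutates the structure object; every bit of a
message is an independent fresh-state evaluation.

## Key stream

Bits are thresholded iterates of the logistic map starting at the *first*
iterate (x₀ emits no bit), with bit = [x ≥ threshold] and ties mapping
to 1; threshold defaults to 0.5. This convention bit-exactly reproduces
the published 24-bit example key from (g = 0.501, μ = 3.68), which is how
it was fixed — the generating rule is otherwise underdetermined.

Arithmetic is IEEE double precision with no rounding between iterates.
One sharp numerical consequence: at g = 0.501 the map derivative
μ(1−2g) ≈ −0.0074 is nearly zero (the critical point is at x = ½), so a
1e-14 perturbation of g *alone* is crushed below one ulp of x₁ and the
two orbits coincide exactly. Sensitivity demonstrations therefore perturb
both parameters (g in the 14th decimal, μ in the 13th), after which the
streams decorrelate to ~50 % disagreement within ~80 iterates. Streams
much longer than a few hundred bits are precision-sensitive by the same
mechanism and should be treated as platform-reproducible only at fixed
IEEE semantics.

## Assembly and the synthetic database

The reference database stands in for a public sequence repository: seeded
uniform-composition strands (default 1000 nt, matching the comparison
point of the security analysis). Real genomic sequence is compositionally
biased and repetitive; nothing in the pipeline depends on composition, but
the repetition risk is real and is handled where it matters — offset
drawing redraws (capped at 1000 attempts) until the four intercepted
16-mers are pairwise distinct *as sequences*, then fails explicitly on
degenerate references such as homopolymers.

Offsets use the published 1-based inclusive interval [1, L−16] at the API
boundary and convert to 0-based slices internally; "intercepted at r"
includes position r, the only reading under which the interval bound keeps
all segments inside the strand. Note the last base of the strand is never
touched (segments end at L−1 at the highest offset); this is inherited
from the interval as printed.

RS1, RS2 and the four toeholds are shipped as fixed package defaults
(distinct, toeholds 6 nt and not substrings of RS1/RS2) because the
scheme treats them as open, reusable sequences but never prints them;
they are overridable per call. Side domains of the lateral triangles are
seeded-random (default 16 nt) subject only to adjacent-face
complementarity — their identity never affects gate logic, only
structural validation.

## Steganography

The offset payload width is fixed at 16 bits (8 nt) per offset — capacity
65535, comfortably above L−16 for kilobase references — because a fixed
width makes the carrier parseable without separators; it is configurable.
The closing primer q′ is the reverse complement of q (primer-pair
convention; the scheme uses the symbol without defining it). The
redundancy tail s₅ is seeded-random, default 20 nt, rejected and redrawn
if it contains q so the primer anchor stays unique. Extraction demands
exactly one pool strand starting with q; zero is "not found", two or more
is an ambiguity error. The q′ check catches frame corruption; a payload
point mutation is detectable only when the decoded integer leaves
[1, L−16] or collides with another offset — an undetected in-range
mutation rebuilds the wrong pyramid and garbles decryption, which is the
expected failure mode of the scheme, not of the implementation.

## Cipher pipelines

The key length always equals the plaintext bit length. The shared secret
is (g, μ, code-table id R, reference id p, primer q); k is derived, never
transmitted. The reference id may be left unset, in which case encryption
draws it (seeded) and records it into the secret set — decryption always
requires it. One structure encrypts one message (per-message seeds); the
module keeps a registry of used (structure, key) pads and logs a warning
on reuse, since pad reuse is the classic one-time-pad break.

The double-bit pipeline pairs the plaintext and key bit streams, maps
codes to strands (00→A' … 11→D'), and serialises the colour spectrum as
one symbol per group (N/R/G/B). Decryption re-runs the same reaction with
the cipher code and key code as inputs and decodes the observed colour —
the XOR involution at the reaction level, not a shortcut bitwise XOR. The
double-bit cipher codes always equal the single-bit cipher bits pairwise
on identical inputs; this scheme agreement is a tested invariant.

## Security model

All probabilities are computed and stored as log₁₀; binomial coefficients
go through log-Γ, and linear-scale values are materialised only for
display (2 significant figures, matching how such tables are printed;
entries below double underflow stay exact in log₁₀ — a printed "−∞" in
this literature is display underflow, not a true zero). The six factors
are exposed individually. One labelling quirk is preserved from the
source analysis: for the single-bit scheme the readout factors are stated
as 1/12 and 1/2 in the equations but with the labels swapped in the text;
the product (1/24) is what matters and is identical either way. The
double-bit total is always exactly 1/24 of the single-bit total at equal
parameters.

`keyspace_estimate` reports (range g = 1) × 10^{digits_g} ×
(range μ = 0.430055) × 10^{digits_μ} with the derivation attached, taking
decimal precisions as parameters because the often-quoted half-×10³²
figure depends on an unstated precision choice; at 16+16 decimals the
estimate is 0.430055×10³².

## Problem sizes

Defaults throughout are the security analysis' comparison point: 1000-nt
reference strands, 5-nt primers, a database of 10 synthetic strands
(selection probability is modelled analytically by N₁ = 1.6×10⁸ in the
security module, so the simulated database only needs to exercise the
machinery), messages of a few bytes in tests and 100-message roundtrip
sweeps per scheme. The full suite runs in well under a minute on one CPU.

## Known limitations

- No thermodynamic sequence design: toeholds and side domains are not
  screened for secondary structure or cross-talk.
- The colour assignments and the green readout are protocol rules (see
  above); a wet-lab realisation would need detector chemistry the model
  does not constrain.
- Keystream quality is not cryptographic: the logistic map is invertible
  given (g, μ) by design, and thresholded orbits are known to be biased;
  the security of the scheme rests on the combinatorial model, not on
  pseudo-randomness claims.
- ASCII only (8-bit big-endian per character); no multi-byte encodings.
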