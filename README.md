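# dnapad

A desk-scale, fully testable model of a **one-time-pad cryptosystem whose
XOR engine is a self-assembled DNA nanostructure**. The package is for
researchers in DNA computing and biomolecular cryptography who want to
study, extend or attack this class of scheme *in silico*: every wet-lab
step — self-assembly, toehold-mediated strand displacement, fluorescence
readout — is replaced by an explicit, rule-level simulator, while every
informational step (encoding, key generation, steganography, security
analysis) is implemented exactly.

## The system

**The calculator.** A pentahedral DNA pyramid: a square base of four 42-nt
edges, each reading RS1–Mᵢ–RS2 (8 + 16 + 18 nt), closed by four lateral
triangular faces A–D. Each face's base strand is the reverse complement of
its edge, preceded by a unique toehold T*ᵢ. Adding the invader strand X'
(fully complementary to face X) displaces that face; the RS1–RS2 joint at
a base corner becomes exposed **iff both faces meeting at that corner are
displaced**. A reporter duplex (RS2 : RS1\*–RS2\*) fluoresces iff some
joint is exposed. Encoding 1 ↦ A' and 0 ↦ B' makes the readout compute
XOR; AND, NOT and OR follow from variations of the same protocol
(pre-displacing face C or D, or adding a strand only for a 1-operand).

**The double-bit calculator.** The four strands A'–D' carry the 2-bit codes
00–11, and three coloured reporters distinguish the outcomes: colourless ↦
00 (same strand twice), red ↦ 01 (corners AB/CD), green ↦ 10 (diagonal
pairs), blue ↦ 11 (corners BC/DA). Each displacement reaction then
computes a full 2-bit XOR: `code(x ⊕ y)` for all 16 input pairs.

**Key stream.** The pad is the thresholded orbit of the logistic map
x_{n+1} = μ·x_n·(1−x_n), x₀ = g, with bitᵢ = [xᵢ ≥ ½]; the shared secret
is just (g, μ) in the chaotic window μ ∈ (3.569945, 4].

**Secret structure, public carrier.** The four secret 16-nt segments
M₁–M₄ are cut from a reference strand p (drawn from a strand database) at
four offsets r₁–r₄ ∈ [1, L−16]. The offsets travel steganographically:
binary-encoded, mapped to bases under one of the 8 complement-consistent
2-bit↔base code tables, and framed as q s₁s₂s₃s₄ q′ s₅ between the secret
primer q, its reverse complement and random redundancy.

**Security model.** An attacker holding only the ciphertext must guess six
independent conventions; the crack probability is

P = 1 / (N₁^{n₁} · C(n−15, 4) · C(4^{n₂}, 2) · 24²)   (single-bit)

and the same with 24³ for the double-bit scheme (N₁ database size, n
reference length, n₁ plaintext bits, n₂ primer length). These underflow
doubles immediately, so the module works in log₁₀ throughout.

## Worked example

```python
from dnapad import SecretKeySet, Seeds, decrypt, encrypt, generate_database

db = generate_database(count=10, length=1000, seed=11)
secrets = SecretKeySet(g=0.501, mu=3.68, table_id=1, q="ACGTA")
record = encrypt("dna", secrets, db, Seeds.from_root(2024), scheme="single")
print(record.spectrum)            # 110110111001101110110110
print(decrypt(record, secrets, db))  # dna
```

The word `"dna"` is the ASCII bit string `011001000110111001100001`; the
logistic key from (g = 0.501, μ = 3.68) is `101111111111010111010111`; the
cipher spectrum `110110111001101110110110` is their XOR, with every bit
produced by a simulated displacement reaction, not by the `^` operator.
Run `dnapad demo` (or any script under `examples/`) to see the full
narrative, including the double-bit colour spectrum
`blue red green …` that decodes to the same cipher bits.

The CLI mirrors the library: `dnapad gen-db`, `build-structure`,
`keystream`, `simulate-gate`, `encrypt`, `decrypt`, `crack-prob`,
`crack-table`, `demo`.

## Layout

- `src/dnapad/` — `codec` (code tables, text↔bits↔DNA), `keystream`
  (logistic map), `assembly` (pyramid construction + synthetic database),
  `stego` (offset hiding/extraction), `displacement` (the rule-based
  strand-displacement simulator), `otp` (both cipher pipelines),
  `security` (crack-probability model), `io`/`config`/`cli` (FASTA,
  configuration, command line).
- `examples/` — one short narrative script per capability.
- `docs/methods.md` — modelling assumptions, parameter choices and
  limitations.
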