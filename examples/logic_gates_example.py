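"""Evaluate Boolean logic on the simulated pyramid calculator.

A bit is carried by an invader strand (A' for 1, B' for 0); the readout
is whether the fluorescence reporter finds an exposed corner joint.
Each row below is one simulated displacement experiment.
"""

from itertools import product

from dnapad import gate

for kind in ("XOR", "AND", "OR"):
    rows = ", ".join(
        f"{a}{b}->{gate(kind, [a, b])}" for a, b in product((0, 1), repeat=2)
    )
    print(f"{kind:>4}: {rows}")
print(f" NOT: 0->{gate('NOT', [0])}, 1->{gate('NOT', [1])}")
print("-> every gate reproduces its Boolean truth table via strand displacement")
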