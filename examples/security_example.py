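"""Closed-form crack probability of the published attack model.

The attacker must guess the reference strand for every plaintext bit,
the four interception sites, the code table, the primer pair and the
readout conventions; the probability is the product of six factors,
evaluated in log10 space because it underflows doubles immediately.
"""

from dnapad import SecurityParams, crack_probability, keyspace_estimate, crack_probability_table
from dnapad.security import format_sci

cp = crack_probability(SecurityParams(N1=1.6e8, n=1000, n1=24, n2=5, scheme="single"))
print("single-bit, 24-bit plaintext:", format_sci(cp.log10_p))
for name, v in cp.components.items():
    print(f"  {name}: log10 = {v:10.3f}")

print()
print(crack_probability_table().to_string(index=False))
print()
est = keyspace_estimate(digits_g=16, digits_mu=16)
print(f"logistic keyspace at 16+16 decimals: {est['size']:.3e}  ({est['derivation']})")
print("-> probabilities fall ~8 orders of magnitude for each extra plaintext byte")
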