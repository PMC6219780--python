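"""Single-bit one-time-pad encryption of the word "dna", end to end.

Each plaintext bit is XOR-ed with a logistic-map key bit by a simulated
strand-displacement reaction; the cipher is the fluorescence spectrum.
The structure's secret segments travel as offsets hidden in a stego
carrier, which the receiver decodes to rebuild the same pyramid.
"""

from dnapad import SecretKeySet, Seeds, decrypt, encrypt, generate_database

db = generate_database(count=10, length=1000, seed=11)
secrets = SecretKeySet(g=0.501, mu=3.68, table_id=1, q="ACGTA")
seeds = Seeds.from_root(2024)

record = encrypt("dna", secrets, db, seeds, scheme="single")
print("cipher spectrum:", record.spectrum)
print("stego carrier:  ", record.carrier.full)
print("reference used: ", secrets.p_id)

plaintext = decrypt(record, secrets, db)
print("decrypted:      ", repr(plaintext))
print("-> the spectrum is the printed cipher 11011011 10011011 10110110;")
print("   only a holder of (g, mu, R, p, q) can rebuild the calculator and invert it")
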