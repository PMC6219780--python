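"""Double-bit encryption: two bits per displacement, read in colour.

The four strands A'..D' carry the codes 00..11; the readout is one of
four colours (colourless/red/green/blue = 00/01/10/11), so each reaction
encrypts a pair of bits.
"""

from dnapad import SecretKeySet, Seeds, decrypt, encrypt, generate_database
from dnapad.displacement import COLOR_TO_CODE, double_bit_xor

# one group in isolation: plaintext pair 01, key pair 10
r = double_bit_xor("01", "10")
print(f"01 xor 10 -> {r.signal} -> cipher {r.code}")

db = generate_database(count=10, length=1000, seed=11)
secrets = SecretKeySet(g=0.501, mu=3.68, table_id=1, q="ACGTA")
record = encrypt("dna", secrets, db, Seeds.from_root(7), scheme="double")

names = {"N": "colorless", "R": "red", "G": "green", "B": "blue"}
print("colour spectrum:", " ".join(names[s] for s in record.spectrum))
print("as cipher bits: ", "".join(COLOR_TO_CODE[names[s]] for s in record.spectrum))
print("decrypted:      ", repr(decrypt(record, secrets, db)))
print("-> 12 colour readouts replace 24 monochrome ones for the same 24-bit message")
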