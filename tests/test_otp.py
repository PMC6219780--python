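"""End-to-end encryption/decryption pipelines."""

import logging

import pytest
from hypothesis import given, settings, strategies as st

import dnapad.otp as otp_mod
from dnapad.otp import CipherRecord, Seeds, SecretKeySet, decrypt, encrypt
from dnapad.sequence import DnaSequence

PRINTED_CIPHER = "110110111001101110110110"

ascii_text = st.text(
    alphabet=st.characters(codec="ascii"), min_size=1, max_size=12
)


class TestSingleBit:
    def test_worked_example_cipher_bits(self, db, secrets, seeds):
        record = encrypt("dna", secrets, db, seeds, scheme="single")
        assert record.spectrum == PRINTED_CIPHER

    def test_worked_example_decrypts_back(self, db, secrets, seeds):
        record = encrypt("dna", secrets, db, seeds, scheme="single")
        assert decrypt(record, secrets, db) == "dna"

    def test_first_bit_case(self, db, secrets, seeds):
        """cipher 1 with key 1 adds strand A' twice: one face, no signal, plain 0."""
        record = encrypt("dna", secrets, db, seeds, scheme="single")
        assert record.spectrum[0] == "1"  # plain 0 XOR key 1
        plain_bits = "011001000110111001100001"
        assert plain_bits[2] == "1"  # third bit: 1 XOR key 1 -> cipher 0
        assert record.spectrum[2] == "0"

    def test_empty_plaintext_still_emits_carrier(self, db, secrets, seeds):
        record = encrypt("", secrets, db, seeds, scheme="single")
        assert record.spectrum == ""
        assert len(record.carrier.full) > 0

    def test_tampered_carrier_raises_corruption(self, db, secrets, seeds):
        record = encrypt("dna", secrets, db, seeds, scheme="single")
        carrier = str(record.carrier.full)
        qp_start = len(secrets.q) + 4 * 8
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        bad = carrier[:qp_start] + flip[carrier[qp_start]] + carrier[qp_start + 1 :]
        with pytest.raises(ValueError, match="corrupted"):
            decrypt(record, secrets, db, pool=[DnaSequence(bad)])

    def test_spectrum_not_multiple_of_8_rejected(self, db, secrets, seeds):
        record = encrypt("dna", secrets, db, seeds, scheme="single")
        bad = CipherRecord("single", record.spectrum[:-1], record.carrier)
        with pytest.raises(ValueError, match="multiple of 8"):
            decrypt(bad, secrets, db)


class TestDoubleBit:
    def test_worked_example_colours(self, db, secrets, seeds):
        record = encrypt("dna", secrets, db, seeds, scheme="double")
        assert record.spectrum[:3] == "BRG"  # blue/11, red/01, green/10

    def test_colour_spectrum_encodes_same_cipher_bits_as_single(self, db, seeds):
        """Scheme agreement: colour codes pairwise equal the single-bit bits."""
        code = {"N": "00", "R": "01", "G": "10", "B": "11"}
        s1 = SecretKeySet(g=0.501, mu=3.68, table_id=1, q="ACGTA")
        s2 = SecretKeySet(g=0.501, mu=3.68, table_id=1, q="ACGTA")
        single = encrypt("dna!", s1, db, seeds, scheme="single")
        double = encrypt("dna!", s2, db, Seeds.from_root(77), scheme="double")
        assert "".join(code[s] for s in double.spectrum) == single.spectrum

    def test_all_zero_plaintext_with_all_zero_key_region(self, db, seeds):
        """NUL plaintext meets key bits directly: colourless only where the
        key pair is 00 too; with both codes equal the readout is always N."""
        secrets = SecretKeySet(g=0.501, mu=3.68, table_id=1, q="ACGTA")
        record = encrypt("\x00\x00\x00", secrets, db, seeds, scheme="double")
        key = "101111111111010111010111"
        for i, sym in enumerate(record.spectrum):
            if key[2 * i : 2 * i + 2] == "00":
                assert sym == "N"

    def test_worked_example_decrypts_back(self, db, secrets, seeds):
        record = encrypt("dna", secrets, db, seeds, scheme="double")
        assert decrypt(record, secrets, db) == "dna"

    def test_first_group_decrypt_path(self, db, secrets, seeds):
        """cipher 11 + key 10 -> strands D',C' -> red -> plaintext 01."""
        from dnapad.displacement import double_bit_xor, demo_structure

        r = double_bit_xor("11", "10", demo_structure())
        assert (r.signal, r.code) == ("red", "01")
        r2 = double_bit_xor("01", "11", demo_structure())
        assert (r2.signal, r2.code) == ("green", "10")


class TestProperties:
    @pytest.mark.parametrize("scheme", ["single", "double"])
    @given(text=ascii_text, root=st.integers(0, 2**20))
    @settings(max_examples=55, deadline=None)
    def test_roundtrip_identity(self, scheme, text, root, db):
        secrets = SecretKeySet(
            g=0.301 + (root % 97) / 1000.0, mu=3.7, table_id=1 + root % 8, q="GATTACA"
        )
        record = encrypt(text, secrets, db, Seeds.from_root(root), scheme=scheme)
        assert decrypt(record, secrets, db) == text

    def test_otp_involution_at_spectrum_level(self, db, secrets, seeds):
        """XOR-ing the cipher spectrum with the same key recovers the plaintext
        bits: encrypt(cipher-as-bits) reproduces the plaintext bit stream."""
        from dnapad.codec import text_to_bits
        from dnapad.displacement import gate
        from dnapad.keystream import KeystreamParams, keystream_bits

        record = encrypt("pad", secrets, db, seeds, scheme="single")
        key = keystream_bits(KeystreamParams(secrets.g, secrets.mu), len(record.spectrum))
        twice = "".join(
            str(gate("XOR", [int(c), int(k)])) for c, k in zip(record.spectrum, key)
        )
        assert twice == text_to_bits("pad")

    def test_pad_reuse_logs_warning(self, db, seeds, caplog):
        secrets = SecretKeySet(g=0.42, mu=3.9, table_id=2, q="CCGGA")
        encrypt("aa", secrets, db, seeds)
        with caplog.at_level(logging.WARNING, logger="dnapad.otp"):
            encrypt("bb", secrets, db, seeds)
        assert any("one-time-pad reuse" in r.message for r in caplog.records)

    def test_fresh_seeds_do_not_warn(self, db, caplog):
        secrets = SecretKeySet(g=0.43, mu=3.9, table_id=2, q="CCGGA")
        with caplog.at_level(logging.WARNING, logger="dnapad.otp"):
            encrypt("aa", secrets, db, Seeds.from_root(1))
            encrypt("bb", secrets, db, Seeds.from_root(2))
        assert not [r for r in caplog.records if "reuse" in r.message]
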