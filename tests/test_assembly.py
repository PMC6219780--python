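"""Pyramid construction, offset drawing and the synthetic database."""

import dataclasses

import pytest
import numpy as np

from dnapad.assembly import (
    ReferenceDatabase,
    build_pyramid,
    draw_offsets,
    generate_database,
    intercept_segments,
    select_reference,
    validate_pyramid,
)
from dnapad.sequence import DnaSequence


class TestDatabase:
    def test_seeded_fasta_is_byte_identical(self, tmp_path):
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        generate_database(10, 100, seed=7).to_fasta(p1)
        generate_database(10, 100, seed=7).to_fasta(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_fasta_roundtrip(self, tmp_path):
        db = generate_database(5, 60, seed=3)
        path = tmp_path / "db.fa"
        db.to_fasta(path)
        assert ReferenceDatabase.from_fasta(path) == db

    def test_boundary_single_minimal_strand(self):
        db = generate_database(1, 17, seed=1)
        assert db.lam == 1
        assert len(db.strands[0][1]) == 17  # offset interval [1, 1]

    def test_strands_pass_alphabet_validation(self):
        for _, seq in generate_database(20, 50, seed=5).strands:
            assert isinstance(DnaSequence(seq), DnaSequence)

    @pytest.mark.parametrize("count,length", [(0, 100), (1, 16)])
    def test_invalid_sizes_rejected(self, count, length):
        with pytest.raises(ValueError):
            generate_database(count, length, seed=0)

    def test_short_strand_rejected_at_construction(self):
        with pytest.raises(ValueError, match="empty"):
            ReferenceDatabase((("x", DnaSequence("ACGT")),))


class TestSelectReference:
    def test_singleton_database(self):
        db = generate_database(1, 100, seed=0)
        assert select_reference(db, seed=5) == ("ref_0001", 100)

    def test_selection_always_within_bounds_and_deterministic(self, db):
        ids = {sid for sid, _ in db.strands}
        for seed in range(200):
            sid, L = select_reference(db, seed)
            assert sid in ids and L == 1000
            assert select_reference(db, seed) == (sid, L)


class TestDrawOffsets:
    def test_all_offsets_within_paper_interval(self, db):
        p = db.strands[0][1]
        offs = draw_offsets(1000, seed=4, p=p)
        assert all(1 <= r <= 984 for r in offs.r)
        assert len(set(offs.r)) == 4

    def test_minimal_interval_cannot_hold_four_offsets(self):
        rng = np.random.default_rng(0)
        p = DnaSequence("".join(rng.choice(list("ACGT"), 17)))
        with pytest.raises(ValueError, match="fewer than four"):
            draw_offsets(17, seed=0, p=p)

    def test_homopolymer_reference_fails_explicitly(self):
        with pytest.raises(RuntimeError, match="repetitive"):
            draw_offsets(100, seed=0, p=DnaSequence("A" * 100), max_attempts=50)

    def test_intercepted_segments_are_distinct(self, db):
        p = db.strands[2][1]
        offs = draw_offsets(1000, seed=9, p=p)
        assert len(set(intercept_segments(p, offs))) == 4


class TestInterceptSegments:
    def test_prefix_interception(self, db):
        from dnapad.assembly import OffsetSet

        p = db.strands[0][1]
        offs = OffsetSet(p_id="x", L=1000, r=(1, 2, 3, 4))
        segs = intercept_segments(p, offs)
        assert str(segs[0]) == str(p)[:16]  # r=1 intercepts the prefix

    def test_agrees_with_substring_oracle(self, db):
        p = db.strands[1][1]
        offs = draw_offsets(1000, seed=13, p=p)
        segs = intercept_segments(p, offs)
        for r, seg in zip(offs.r, segs):
            assert len(seg) == 16
            assert str(p)[r - 1 : r + 15] == str(seg)  # 1-based inclusive start

    def test_upper_bound_offset_stays_inside_strand(self, db):
        from dnapad.assembly import OffsetSet

        p = db.strands[0][1]
        offs = OffsetSet(p_id="x", L=1000, r=(984, 1, 2, 3))
        segs = intercept_segments(p, offs)
        assert str(segs[0]) == str(p)[983:999]  # ends at position L-1


def _structure(db, seed=0):
    p = db.strands[0][1]
    offs = draw_offsets(1000, seed=seed, p=p)
    return build_pyramid(intercept_segments(p, offs), seed=seed)


class TestBuildPyramid:
    def test_every_edge_is_42_nt(self, db):
        s = _structure(db)
        assert all(len(e) == 42 for e in s.edges)

    def test_face_base_is_revcomp_of_edge(self, db):
        s = _structure(db)
        for face, edge in zip(s.faces, s.edges):
            assert face.base_pairing_region == edge.revcomp()
            assert face.base.startswith(face.toehold)

    def test_input_strand_is_full_complement_of_face(self, db):
        s = _structure(db)
        f = s.face("A")
        full_face = DnaSequence(f.side_prev + f.base + f.side_next)
        assert s.input_strand("A") == full_face.revcomp()

    def test_hundred_seeded_builds_all_validate(self, db):
        for seed in range(100):
            report = validate_pyramid(_structure(db, seed))
            assert report.passed, report.failures()

    def test_duplicate_segments_rejected(self, db):
        m = DnaSequence("ACGT" * 4)
        with pytest.raises(ValueError, match="distinct"):
            build_pyramid((m, m, DnaSequence("A" * 16), DnaSequence("C" * 16)))

    def test_wrong_segment_length_rejected(self):
        with pytest.raises(ValueError, match="16"):
            build_pyramid(tuple(DnaSequence("ACGT") for _ in range(4)))


class TestValidatePyramid:
    def test_short_segment_reported_by_name(self, db):
        s = _structure(db)
        bad_M = (s.M[0], DnaSequence(s.M[1][:15]), s.M[2], s.M[3])
        broken = dataclasses.replace(s, M=bad_M)
        failures = validate_pyramid(broken).failures()
        assert any("M2 length" in name for name, _ in failures)

    def test_mutated_face_base_fails_complementarity(self, db):
        s = _structure(db)
        f = s.faces[0]
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        mutated = f.base[:-1] + flip[f.base[-1]]
        bad_face = dataclasses.replace(f, base=DnaSequence(mutated))
        broken = dataclasses.replace(s, faces=(bad_face,) + s.faces[1:])
        failures = validate_pyramid(broken).failures()
        assert any("face A complementarity" in name for name, _ in failures)

    def test_duplicate_segments_fail_distinctness(self, db):
        s = _structure(db)
        broken = dataclasses.replace(s, M=(s.M[0], s.M[1], s.M[0], s.M[3]))
        failures = validate_pyramid(broken).failures()
        assert any("M distinct" in name for name, _ in failures)
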