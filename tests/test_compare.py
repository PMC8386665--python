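"""Molecule comparison: blocks, shared/unique, rearrangements, flanks."""

import numpy as np
import pytest

from mitostruct.compare import (
    anchor_blocks,
    breakpoint_flanks,
    detect_rearrangements,
    report_intergenic,
    shared_unique,
)
from mitostruct.fileio import GffFeature
from mitostruct.sequence import CircularSequence, Interval, revcomp, rotate
from mitostruct.simulate import make_insertion_pair, make_translocation_pair

from conftest import random_circle


class TestAnchorBlocks:
    def test_identical_sequences_one_full_block(self, rng):
        s = random_circle(rng, 8_000)
        t = CircularSequence("t", s.seq, "circular")
        blocks = anchor_blocks(s, t)
        assert len(blocks) == 1
        assert blocks[0].length == 8_000 and blocks[0].strand == "+"

    def test_reverse_complement_one_minus_block(self, rng):
        s = random_circle(rng, 8_000)
        t = CircularSequence("t", revcomp(s.seq), "circular")
        blocks = anchor_blocks(s, t)
        assert len(blocks) == 1
        assert blocks[0].length == 8_000 and blocks[0].strand == "-"

    def test_disjoint_random_sequences_share_nothing(self, rng):
        a = random_circle(rng, 6_000, "a")
        b = random_circle(rng, 6_000, "b")
        summary = shared_unique(anchor_blocks(a, b), 6_000, 6_000)
        assert summary.shared == 0

    def test_shared_unique_identity_on_self(self, rng):
        s = random_circle(rng, 5_000)
        t = CircularSequence("t", s.seq, "circular")
        summary = shared_unique(anchor_blocks(s, t), 5_000, 5_000)
        assert (summary.shared, summary.uniqueA, summary.uniqueB) == (5_000, 0, 0)

    def test_shared_unique_on_constructed_mixture(self, rng):
        """Molecules built as shared core + unique arms (the molecule-1a/1b
        structure, scaled): summary matches construction within 1%."""
        shared_len, ua, ub = 21_900, 7_730, 980
        core = "".join(rng.choice(list("ACGT"), shared_len))
        a = CircularSequence(
            "a", core + "".join(rng.choice(list("ACGT"), ua)), "circular"
        )
        b = CircularSequence(
            "b", core + "".join(rng.choice(list("ACGT"), ub)), "circular"
        )
        summary = shared_unique(anchor_blocks(a, b), len(a), len(b))
        assert summary.shared == pytest.approx(shared_len, rel=0.01)
        assert summary.uniqueA == pytest.approx(ua, rel=0.01, abs=60)
        assert summary.uniqueB == pytest.approx(ub, rel=0.01, abs=60)


class TestDetectRearrangements:
    def test_identical_molecules_no_events(self, rng):
        s = random_circle(rng, 8_000)
        t = CircularSequence("t", s.seq, "circular")
        assert detect_rearrangements(anchor_blocks(s, t), s, t) == []

    def test_translocation_fixture_single_774_event(self):
        a, b, truth = make_translocation_pair(seed=41)
        events = detect_rearrangements(anchor_blocks(a, b), a, b)
        translocations = [e for e in events if e.type == "translocation"]
        assert len(translocations) == 1
        assert translocations[0].block_length == truth.translocation["block_length"]
        assert [e.type for e in events] == ["translocation"]

    def test_insertion_fixture_single_event(self):
        a, b, truth = make_insertion_pair(seed=42, molecule_length=30_000)
        events = detect_rearrangements(anchor_blocks(a, b), a, b)
        insertions = [e for e in events if e.type == "insertion"]
        assert len(insertions) == 1
        # inserted arc carries the block plus one extra flank copy
        assert insertions[0].block_length == 774 + 40

    def test_swap_duality_insertion_becomes_deletion(self):
        a, b, _ = make_insertion_pair(seed=43, molecule_length=30_000)
        fwd = detect_rearrangements(anchor_blocks(a, b), a, b)
        rev = detect_rearrangements(anchor_blocks(b, a), b, a)
        assert [e.type for e in fwd] == ["insertion"]
        assert [e.type for e in rev] == ["deletion"]
        assert fwd[0].block_length == rev[0].block_length

    def test_rotation_changes_no_event(self):
        a, b, _ = make_translocation_pair(seed=44, molecule_length=20_000)
        base = sorted(
            (e.type, e.block_length)
            for e in detect_rearrangements(anchor_blocks(a, b), a, b)
        )
        for ka, kb in [(1_234, 7_777), (9_999, 3)]:
            ra, rb = rotate(a, ka), rotate(b, kb)
            got = sorted(
                (e.type, e.block_length)
                for e in detect_rearrangements(anchor_blocks(ra, rb), ra, rb)
            )
            assert got == base

    def test_inversion_block_classified(self, rng):
        core = rng.choice(list("ACGT"), 12_000)
        a = CircularSequence("a", "".join(core), "circular")
        flipped = core.copy()
        flipped[4_000:6_000] = list(revcomp("".join(core[4_000:6_000])))
        b = CircularSequence("b", "".join(flipped), "circular")
        events = detect_rearrangements(anchor_blocks(a, b), a, b)
        inversions = [e for e in events if e.type == "inversion"]
        assert len(inversions) == 1
        assert inversions[0].block_length == pytest.approx(2_000, abs=5)


class TestBreakpointFlanks:
    def test_translocation_flank_is_40(self):
        a, b, _ = make_translocation_pair(seed=45)
        events = detect_rearrangements(anchor_blocks(a, b), a, b)
        ev = next(e for e in events if e.type == "translocation")
        flank = breakpoint_flanks(ev, a, b, window=500)
        assert flank is not None and flank.length == 40

    def test_insertion_flank_is_40(self):
        a, b, _ = make_insertion_pair(seed=46, molecule_length=30_000)
        ev = next(
            e
            for e in detect_rearrangements(anchor_blocks(a, b), a, b)
            if e.type == "insertion"
        )
        flank = breakpoint_flanks(ev, a, b, window=500)
        assert flank is not None and flank.length == 40

    def test_custom_flank_length_recovered(self):
        a, b, _ = make_translocation_pair(flank_len=60, seed=47)
        ev = next(
            e
            for e in detect_rearrangements(anchor_blocks(a, b), a, b)
            if e.type == "translocation"
        )
        flank = breakpoint_flanks(ev, a, b, window=500)
        assert flank is not None and flank.length == 60

    def test_event_without_flank_returns_none(self, rng):
        """A block moved without any planted flanking repeat."""
        u = "".join(rng.choice(list("ACGT"), 9_000))
        v = "".join(rng.choice(list("ACGT"), 6_000))
        w = "".join(rng.choice(list("ACGT"), 5_000))
        blk = "".join(rng.choice(list("ACGT"), 800))
        a = CircularSequence("a", u + blk + v + w, "circular")
        b = CircularSequence("b", u + v + blk + w, "circular")
        events = detect_rearrangements(anchor_blocks(a, b), a, b)
        ev = next(e for e in events if e.type == "translocation")
        assert breakpoint_flanks(ev, a, b, window=500) is None


class TestReportIntergenic:
    @pytest.mark.parametrize("gap", [637, 638])
    def test_marker_region_distance(self, rng, gap):
        """The cob-fragment to rps10 marker distance on a built fixture."""
        feats = [
            GffFeature("m", "t", "pseudogene", Interval(1_000, 300, "+"), ".", {"ID": "psi-cob"}),
            GffFeature("m", "t", "gene", Interval(1_300 + gap, 500, "+"), ".", {"ID": "rps10"}),
        ]
        assert report_intergenic(feats, "psi-cob", "rps10", 20_000) == gap

    def test_missing_feature_raises(self):
        with pytest.raises(KeyError):
            report_intergenic([], "psi-cob", "rps10", 1_000)
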