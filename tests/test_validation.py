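"""Reverse read mapping: support counting, sensitivity, specificity."""

import numpy as np
import pytest

from mitostruct.fileio import PafRecord
from mitostruct.recombination import enumerate_all, predict_junctions
from mitostruct.repeats import RepeatParams, find_repeats
from mitostruct.sequence import revcomp
from mitostruct.simulate import (
    ReadSimParams,
    realize_genome,
    simulate_reads,
    single_repeat_profile,
)
from mitostruct.validation import (
    ValidationParams,
    alignments_from_paf,
    count_support,
    map_reads,
    validate_genome,
)


@pytest.fixture(scope="module")
def small_genome():
    """A 24 kb circle with a direct 800 bp repeat pair and its products."""
    from mitostruct.repeats import RepeatParams

    prof = single_repeat_profile(24_000, 800, "direct", spacing=9_000)
    seqs, _ = realize_genome(prof, seed=21)
    parent = seqs[0]
    products = enumerate_all(parent, find_repeats(parent, RepeatParams(min_len=500)))
    return parent, products


PARAMS = ValidationParams(min_anchor=300, min_reads=3, min_identity=0.85)


def _junctions(products, min_anchor=300):
    out = []
    for prod in products:
        w = (prod.repeat_length + 1) // 2 + min_anchor + PARAMS.flank_margin
        out += [j for j in predict_junctions(prod, w) if j.novel]
    return out


def _reads(sources, seed, coverage=25, sub=0.0, indel=0.0):
    reads, _ = simulate_reads(
        sources,
        ReadSimParams(
            coverage=coverage,
            length_mu=np.log(4_000),
            length_sigma=0.25,
            min_len=2_500,
            max_len=8_000,
            sub_rate=sub,
            indel_rate=indel,
            seed=seed,
        ),
    )
    return [(r.id, r.seq) for r in reads]


class TestMapReads:
    def test_error_free_junction_read_maps_at_full_identity(self, small_genome):
        parent, products = small_genome
        j = _junctions(products)[0]
        read = j.construct  # a perfect read across the junction
        recs = map_reads([("r0", read)], [(j.id, j.construct)], PARAMS)
        assert len(recs) == 1
        assert recs[0].identity == 1.0
        assert (recs[0].target_start, recs[0].target_end) == (0, len(j.construct))

    def test_reverse_strand_read_maps(self, small_genome):
        _, products = small_genome
        j = _junctions(products)[0]
        recs = map_reads([("r0", revcomp(j.construct))], [(j.id, j.construct)], PARAMS)
        assert recs and recs[0].strand == "-" and recs[0].identity == 1.0

    def test_shuffled_decoy_read_does_not_map(self, small_genome, rng):
        _, products = small_genome
        j = _junctions(products)[0]
        decoy = "".join(rng.permutation(list(j.construct)))
        recs = map_reads([("d0", decoy)], [(j.id, j.construct)], PARAMS)
        assert all(r.identity < PARAMS.min_identity for r in recs)

    def test_empty_read_set_is_empty_output(self, small_genome):
        _, products = small_genome
        j = _junctions(products)[0]
        assert map_reads([], [(j.id, j.construct)], PARAMS) == []


class TestCountSupport:
    def test_mixture_reads_support_all_novel_junctions(self, small_genome):
        parent, products = small_genome
        junctions = _junctions(products)
        assert len(junctions) == 2
        subs = [p.as_sequence() for p in products]
        reads = _reads([(subs[0], 0.5), (subs[1], 0.5)], seed=31)
        alignments = map_reads(reads, [(j.id, j.construct) for j in junctions], PARAMS)
        support = count_support(alignments, junctions, PARAMS)
        assert all(s.supported for s in support)
        assert all(s.n_spanning <= s.n_total for s in support)

    def test_parent_only_reads_support_nothing(self, small_genome):
        parent, products = small_genome
        junctions = _junctions(products)
        reads = _reads([(parent, 1.0)], seed=32)
        alignments = map_reads(reads, [(j.id, j.construct) for j in junctions], PARAMS)
        support = count_support(alignments, junctions, PARAMS)
        assert all(s.n_spanning == 0 for s in support)
        assert not any(s.supported for s in support)

    def test_sensitivity_across_seeds_with_errors(self, small_genome):
        """Junctions of present isoforms are supported at 5% error, 10 seeds."""
        parent, products = small_genome
        junctions = _junctions(products)
        constructs = [(j.id, j.construct) for j in junctions]
        subs = [p.as_sequence() for p in products]
        for seed in range(40, 50):
            reads = _reads([(subs[0], 0.5), (subs[1], 0.5)], seed=seed,
                           coverage=40, sub=0.04, indel=0.01)
            support = count_support(
                map_reads(reads, constructs, PARAMS), junctions, PARAMS
            )
            assert all(s.supported for s in support), f"seed {seed}"

    def test_specificity_absent_isoform_with_errors(self, small_genome):
        """Reads only from one sub-circle leave the other junction unsupported."""
        parent, products = small_genome
        junctions = _junctions(products)
        constructs = [(j.id, j.construct) for j in junctions]
        subs = [p.as_sequence() for p in products]
        present = products[0].id
        reads = _reads([(subs[0], 1.0)], seed=51, sub=0.04, indel=0.01)
        support = count_support(map_reads(reads, constructs, PARAMS), junctions, PARAMS)
        by_junction = {s.junction_id: s for s in support}
        for j in junctions:
            if j.id.startswith(present):
                assert by_junction[j.id].supported
            else:
                assert by_junction[j.id].n_spanning < PARAMS.min_reads

    def test_support_invariant_to_read_order(self, small_genome):
        parent, products = small_genome
        junctions = _junctions(products)
        constructs = [(j.id, j.construct) for j in junctions]
        subs = [p.as_sequence() for p in products]
        reads = _reads([(subs[0], 0.5), (subs[1], 0.5)], seed=33)
        fwd = count_support(map_reads(reads, constructs, PARAMS), junctions, PARAMS)
        rev = count_support(map_reads(reads[::-1], constructs, PARAMS), junctions, PARAMS)
        assert fwd == rev

    def test_huge_anchor_requirement_yields_zero_spanning(self, small_genome):
        parent, products = small_genome
        junctions = _junctions(products, min_anchor=300)
        subs = [p.as_sequence() for p in products]
        reads = _reads([(subs[0], 0.5), (subs[1], 0.5)], seed=34)
        params = ValidationParams(min_anchor=10_000, min_reads=3)
        with pytest.raises(ValueError, match="anchor requirement"):
            count_support(
                map_reads(reads, [(j.id, j.construct) for j in junctions], params),
                junctions,
                params,
            )

    def test_unknown_junction_target_raises(self, small_genome):
        _, products = small_genome
        junctions = _junctions(products)
        paf = PafRecord("r1", 4000, 0, 2000, "+", "nonexistent", 2000, 0, 2000, 2000, 2000, 60)
        with pytest.raises(KeyError, match="nonexistent"):
            count_support(alignments_from_paf([paf]), junctions, PARAMS)

    def test_paf_import_matches_internal_mapper_on_error_free_reads(self, small_genome):
        """Cross-check: truth-derived PAF gives the same support calls."""
        parent, products = small_genome
        junctions = _junctions(products)
        constructs = {j.id: j.construct for j in junctions}
        subs = {p.id: p.as_sequence() for p in products}
        reads_raw, truth = simulate_reads(
            [(subs[p.id], 1.0 / len(subs)) for p in products],
            ReadSimParams(coverage=20, length_mu=np.log(4_000), length_sigma=0.25,
                          min_len=2_500, max_len=8_000, seed=35),
        )
        # build PAF from read provenance: an error-free read covers exactly
        # the construct positions its source interval overlaps on the
        # product circle (independent of the mapper under test)
        by_product = {j.id: j for j in junctions}
        paf_records = []
        for r in reads_raw:
            src = subs[r.source_id]
            for jid, construct in constructs.items():
                if not jid.startswith(r.source_id):
                    continue
                j = by_product[jid]
                w = len(j.left)
                Lp = len(src)
                window_start = (j.position - w) % Lp
                off = (r.start - window_start) % Lp
                rl = len(r.seq)
                segments = []
                if off < 2 * w:
                    segments.append((off, min(off + rl, 2 * w)))
                if off + rl > Lp:
                    segments.append((0, min(off + rl - Lp, 2 * w)))
                segments = [s for s in segments if s[1] > s[0]]
                if not segments:
                    continue
                t0, t1 = max(segments, key=lambda s: s[1] - s[0])
                paf_records.append(
                    PafRecord(r.id, rl, 0, t1 - t0, r.strand, jid,
                              len(construct), t0, t1, t1 - t0, t1 - t0, 60)
                )
        internal = count_support(
            map_reads([(r.id, r.seq) for r in reads_raw],
                      list(constructs.items()), PARAMS),
            junctions,
            PARAMS,
        )
        external = count_support(alignments_from_paf(paf_records), junctions, PARAMS)
        assert {s.junction_id: s.supported for s in internal} == {
            s.junction_id: s.supported for s in external
        }
        assert {s.junction_id: s.n_spanning for s in internal} == {
            s.junction_id: s.n_spanning for s in external
        }


class TestValidateGenome:
    def test_end_to_end_supported_junctions(self, small_genome):
        parent, products = small_genome
        subs = [p.as_sequence() for p in products]
        reads = _reads([(subs[0], 0.5), (subs[1], 0.5)], seed=36)
        table = validate_genome([parent], reads, PARAMS,
                                repeat_params=RepeatParams(min_len=500), flank_w=500)
        assert len(table) == 2
        assert table["supported"].all()

    def test_molecule_without_repeats_gives_empty_table(self, rng):
        from conftest import random_circle

        mol = random_circle(rng, 20_000)
        table = validate_genome([mol], [], PARAMS)
        assert table.empty

    def test_deterministic_given_inputs(self, small_genome):
        parent, products = small_genome
        subs = [p.as_sequence() for p in products]
        reads = _reads([(subs[0], 0.5), (subs[1], 0.5)], seed=37)
        t1 = validate_genome([parent], reads, PARAMS,
                             repeat_params=RepeatParams(min_len=500), flank_w=500)
        t2 = validate_genome([parent], reads, PARAMS,
                             repeat_params=RepeatParams(min_len=500), flank_w=500)
        assert t1.equals(t2)
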