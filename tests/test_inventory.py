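"""Gene inventory: ORF discovery, stop checks, category counts, matrices."""

import numpy as np
import pytest

from mitostruct.inventory import (
    CONSERVED_GENES,
    PHYLOGENY_MARKER_GENES,
    GeneAnnotation,
    annotation_from_gff,
    categorize,
    check_internal_stops,
    find_orfs,
    group_specific,
    presence_absence,
    summarize,
)
from mitostruct.sequence import CircularSequence, Interval, revcomp

_STOPS = {"TAA", "TAG", "TGA"}
_SAFE_CODONS = ["GCT", "GAA", "TTC", "CTG", "AAA", "GGC", "CCA", "TCT"]


def _sixframe_oracle(s: CircularSequence, min_codons: int):
    """Brute-force six-frame closed-ORF scan on the doubled sequence."""
    L = len(s)
    found = set()
    for strand in ("+", "-"):
        scan = (s.seq if strand == "+" else revcomp(s.seq)) * 2
        for frame in range(3):
            open_at = None
            for i in range(frame, len(scan) - 2, 3):
                codon = scan[i : i + 3]
                if codon in _STOPS:
                    if open_at is not None and (i - open_at) // 3 > min_codons:
                        if open_at < L and (i + 3 - open_at) <= L:
                            found.add((open_at % L, strand, (i - open_at) // 3))
                    open_at = None
                elif open_at is None and codon == "ATG":
                    open_at = i
    return found


def _stopfree(rng, n_codons):
    return "".join(rng.choice(_SAFE_CODONS, n_codons))


class TestFindOrfs:
    def test_matches_sixframe_oracle_on_random_circles(self):
        for seed in range(3):
            rng = np.random.default_rng(600 + seed)
            s = CircularSequence(
                "r", "".join(rng.choice(list("ACGT"), 4_000)), "circular"
            )
            L = len(s)
            got = {
                (o.iv.start, o.strand, o.length_codons)
                for o in find_orfs(s, min_codons=30)
            }
            oracle = set()
            for start, strand, n in _sixframe_oracle(s, 30):
                if strand == "-":  # map the RC-space start to forward coords
                    start = (L - start - 3 * (n + 1)) % L
                oracle.add((start, strand, n))
            assert got == oracle

    def test_planted_minus_strand_orf_crossing_origin(self, rng):
        core = "ATG" + _stopfree(rng, 149) + "TGA"  # 150 coding codons + stop
        plus_strand = revcomp(core)
        filler = "".join(rng.choice(["TAA"], 400))  # stop-rich background
        seq = plus_strand[-200:] + filler + plus_strand[:-200]
        s = CircularSequence("o", seq, "circular")
        hits = [o for o in find_orfs(s, min_codons=100) if o.strand == "-"]
        assert [o.length_codons for o in hits] == [150]

    def test_poly_a_has_no_closed_orfs(self):
        s = CircularSequence("a", "A" * 3_000, "circular")
        assert find_orfs(s, min_codons=10) == []

    def test_threshold_is_exclusive(self, rng):
        """An ORF of exactly min_codons codons is excluded ('larger than')."""
        core = "ATG" + _stopfree(rng, 99) + "TAA"  # 100 coding codons
        seq = "TAATAATAA" + core + "TAATAATAA"
        s = CircularSequence("t", seq, "linear")
        assert find_orfs(s, min_codons=100) == []
        assert [o.length_codons for o in find_orfs(s, min_codons=99)] == [100]


class TestInternalStops:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATGTAATGA", True), ("ATGAAATGA", False)],
    )
    def test_simple_cases(self, seq, expected):
        has, _ = check_internal_stops(seq)
        assert has is expected

    def test_stop_free_construct(self, rng):
        seq = "ATG" + _stopfree(rng, 298) + "TAA"
        has, positions = check_internal_stops(seq)
        assert has is False and positions == []

    def test_frame_error(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            check_internal_stops("ATGT")


def _conserved_annotations():
    out = []
    pos = 0
    for cat, genes in CONSERVED_GENES.items():
        for g in genes:
            out.append(
                GeneAnnotation(g, cat, Interval(pos, 100, "+"), "m1")
            )
            pos += 200
    return out


class TestSummarize:
    def test_conserved_gene_list_counts(self):
        """The conserved potato mtDNA complement: 9 nad, 5 atp, 11 ribosomal
        proteins, 4 ccm, 3 cox, 2 sdh."""
        report = summarize(_conserved_annotations())
        assert report.counts["nad"] == 9
        assert report.counts["atp"] == 5
        assert report.counts["rps_rpl"] == 11
        assert report.counts["ccm"] == 4
        assert report.counts["cox"] == 3
        assert report.counts["sdh"] == 2

    def test_phylogeny_marker_set_has_33_genes(self):
        assert len(PHYLOGENY_MARKER_GENES) == 33
        assert len(set(PHYLOGENY_MARKER_GENES)) == 33

    def test_empty_annotations_all_zero(self):
        report = summarize([])
        assert all(v == 0 for v in report.counts.values())

    def test_pseudo_counted_separately(self):
        anns = [
            GeneAnnotation("cob", "cob", Interval(0, 100, "+"), "m1"),
            GeneAnnotation("Ψcob", "cob", Interval(200, 80, "+"), "m1", pseudo=True),
        ]
        counts = summarize(anns).counts
        assert counts["cob"] == 1 and counts["pseudo"] == 1

    def test_plastid_derived_classification(self):
        assert categorize("petA") == "plastid_derived"
        assert categorize("rpl23") == "plastid_derived"
        assert categorize("rpl2") == "rps_rpl"

    def test_unknown_gene_rejected(self):
        from mitostruct.fileio import GffFeature

        feats = [
            GffFeature("m1", "t", "gene", Interval(0, 90, "+"), ".", {"ID": "mystery1"})
        ]
        with pytest.raises(KeyError, match="mystery1"):
            annotation_from_gff(feats)
        anns = annotation_from_gff(feats, categories={"mystery1": "orf"})
        assert anns[0].category == "orf"


class TestPresenceAbsence:
    GENOMES = {
        "groupA": ["orf137", "orf125", "orf123", "cob"],
        "groupB": ["orf123", "cob"],
        "10908-06": ["orf137", "cob"],
        "OKA15": ["orf123", "cob"],
    }

    def test_matrix_shape_and_counts(self):
        m = presence_absence(self.GENOMES)
        assert m.shape == (4, 4)
        assert m["groupA"].sum() == 4 and m["groupB"].sum() == 2

    def test_group_specific_report(self):
        m = presence_absence(self.GENOMES)
        groups = {g: [g] for g in self.GENOMES}
        report = group_specific(m, groups)
        assert report.get("10908-06+groupA") == ["orf137"]
        assert report.get("groupA") == ["orf125"]
        assert "cob" not in [g for genes in report.values() for g in genes]

    def test_all_shared_gives_empty_report(self):
        m = presence_absence({"a": ["x", "y"], "b": ["x", "y"]})
        assert group_specific(m, {"a": ["a"], "b": ["b"]}) == {}

    def test_single_genome_matrix(self):
        m = presence_absence({"only": ["x", "y"]})
        assert m.shape == (2, 1) and m["only"].all()

    def test_duplicate_genome_ids_rejected(self):
        with pytest.raises(ValueError, match="at least one|duplicate"):
            presence_absence({})
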