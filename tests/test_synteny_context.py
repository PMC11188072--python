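import numpy as np
import pytest
from scipy import stats

from ismorf.intergenic_orfs import IntergenicRegion, IsmOrf
from ismorf.io_formats import FeatureRecord
from ismorf.synteny_context import (
    ContextRecord,
    LcbBlock,
    build_syn_igs,
    classify_orientation,
    fisher_exact_2x2,
    intersect_igs_lcbs,
    orientation_enrichment,
    turnover_profile,
)


def _ig(ig_id, genome, start, end, left=None, right=None):
    return IntergenicRegion(ig_id, genome, f"{genome}_c1", start, end, left, right)


def _orf(orf_id, ig, start, end, strand="+"):
    n_aa = (end - start) // 3 - 1
    return IsmOrf(orf_id, ig.ig_id, ig.genome_id, ig.contig_id, start, end,
                  strand, "ATG", "M" + "A" * (n_aa - 1), 1.0)


class TestIntersect:
    def test_full_overlap_kept(self):
        igs = [_ig("ig1", "gA", 100, 200)]
        lcbs = [LcbBlock("b1", "gA", "gA_c1", 50, 400)]
        assert intersect_igs_lcbs(igs, lcbs) == [("ig1", "b1", 1.0)]

    def test_forty_percent_dropped(self):
        igs = [_ig("ig1", "gA", 100, 200)]
        lcbs = [LcbBlock("b1", "gA", "gA_c1", 160, 400)]
        assert intersect_igs_lcbs(igs, lcbs) == []

    def test_boundary_half_kept(self):
        igs = [_ig("ig1", "gA", 100, 200)]
        lcbs = [LcbBlock("b1", "gA", "gA_c1", 150, 400)]
        assert intersect_igs_lcbs(igs, lcbs) == [("ig1", "b1", 0.5)]

    def test_empty_lcbs(self):
        assert intersect_igs_lcbs([_ig("ig1", "gA", 0, 100)], []) == []

    def test_unknown_contig_skipped(self):
        igs = [_ig("ig1", "gA", 100, 200)]
        lcbs = [LcbBlock("b1", "gZ", "gZ_c1", 0, 400)]
        assert intersect_igs_lcbs(igs, lcbs) == []


def _toy_synteny(n_species=3, with_coding=True, intact_in=None):
    igs, orfs, pairs = [], [], []
    intact_in = set(range(n_species)) if intact_in is None else intact_in
    for g in range(n_species):
        ig = _ig(f"ig{g}", f"sp{g}_genome", 100, 400)
        igs.append(ig)
        pairs.append((ig.ig_id, "b1", 1.0))
        if g in intact_in:
            orfs.append(_orf(f"o{g}", ig, 150, 210))
    orf_clusters = {o.orf_id: "clusterX" for o in orfs}
    coding = {"clusterX"} if with_coding else set()
    return pairs, igs, orfs, coding, orf_clusters


class TestBuildSynIgs:
    def test_shared_block_across_species(self):
        blocks = build_syn_igs(*_toy_synteny())
        assert len(blocks) == 1
        assert len(blocks[0].species_set) == 3
        assert blocks[0].clusters_present == {"clusterX"}

    def test_single_species_rejected(self):
        pairs, igs, orfs, coding, oc = _toy_synteny(3)
        species = {f"sp{g}_genome": "same_species" for g in range(3)}
        assert build_syn_igs(pairs, igs, orfs, coding, oc, species) == []

    def test_no_coding_ismorf_rejected(self):
        blocks = build_syn_igs(*_toy_synteny(with_coding=False))
        assert blocks == []

    def test_filters_match_brute_force(self, rng):
        # randomized toy tables vs direct re-application of the 3 predicates
        for _ in range(30):
            n_genomes = int(rng.integers(2, 6))
            igs = [_ig(f"ig{g}", f"sp{int(rng.integers(3))}_g{g}", 0, 300)
                   for g in range(n_genomes)]
            pairs = [(ig.ig_id, f"b{int(rng.integers(2))}", 1.0) for ig in igs]
            orfs = []
            for ig in igs:
                if rng.random() < 0.5:
                    orfs.append(_orf(f"o_{ig.ig_id}", ig, 10, 70))
            coding = {"cX"} if rng.random() < 0.8 else set()
            oc = {o.orf_id: "cX" for o in orfs}
            blocks = build_syn_igs(pairs, igs, orfs, coding, oc)
            ig_by_id = {ig.ig_id: ig for ig in igs}
            expected = 0
            for b in {p[1] for p in pairs}:
                members = [p[0] for p in pairs if p[1] == b]
                species = {ig_by_id[m].genome_id.split("_")[0] for m in members}
                has_coding = any(o.ig_id in members and oc[o.orf_id] in coding
                                 for o in orfs)
                if len(species) >= 2 and has_coding:
                    expected += 1
            assert len(blocks) == expected


class TestTurnover:
    def test_fraction_intact(self):
        blocks = build_syn_igs(*_toy_synteny(4, intact_in={0, 1, 2}))
        table = turnover_profile(blocks)
        assert len(table) == 1
        assert table.fraction_intact[0] == pytest.approx(0.75)

    def test_all_intact(self):
        blocks = build_syn_igs(*_toy_synteny(4))
        table = turnover_profile(blocks)
        assert table.fraction_intact[0] == 1.0


def _flank(start, end, strand):
    return FeatureRecord("c1", start, end, strand, f"f{start}")


class TestOrientation:
    def _case(self, orf_strand, left_strand, right_strand,
              orf_start=100, orf_end=160):
        ig = IntergenicRegion("ig1", "g1", "c1", 50, 250,
                              left_gene=_flank(0, 50, left_strand),
                              right_gene=_flank(250, 300, right_strand))
        orf = _orf("o1", ig, orf_start, orf_end, orf_strand)
        return classify_orientation(orf, ig)

    def test_codirected_downstream(self):
        rec = self._case("+", "-", "+")
        assert rec.downstream_relation == "collinear"
        assert rec.upstream_relation == "divergent"

    def test_head_to_head_upstream(self):
        rec = self._case("+", "-", "-")
        assert rec.upstream_relation == "divergent"
        assert rec.downstream_relation == "convergent"

    def test_minus_strand_flank_swap(self):
        rec = self._case("-", "+", "-")
        # upstream of a '-' ORF is the right flank ('-' -> collinear);
        # downstream is the left flank ('+' vs '-' -> convergent)
        assert rec.upstream_relation == "collinear"
        assert rec.downstream_relation == "convergent"

    def test_distances_and_proximity(self):
        ig = IntergenicRegion("ig1", "g1", "c1", 50, 250,
                              left_gene=_flank(0, 50, "+"),
                              right_gene=_flank(204, 300, "+"))
        orf = _orf("o1", ig, 140, 200, "+")
        rec = classify_orientation(orf, ig)
        assert rec.dist_downstream == 4 and rec.near_downstream
        assert rec.dist_upstream == 90
        assert not rec.overlap_1_4

    def test_short_overlap_flag(self):
        ig = IntergenicRegion("ig1", "g1", "c1", 50, 250,
                              left_gene=_flank(0, 50, "+"),
                              right_gene=_flank(198, 300, "+"))
        orf = _orf("o1", ig, 140, 200, "+")
        rec = classify_orientation(orf, ig)
        assert rec.dist_downstream == -2 and rec.overlap_1_4
        assert rec.near_downstream is False

    def test_missing_flank_relation_none(self):
        ig = IntergenicRegion("ig1", "g1", "c1", 50, 250, left_gene=None,
                              right_gene=_flank(250, 300, "+"))
        rec = classify_orientation(_orf("o1", ig, 100, 160, "+"), ig)
        assert rec.upstream_relation == "none" and rec.dist_upstream is None

    def test_strand_covariance(self, rng):
        # reverse-complementing the contig leaves relation labels unchanged
        L = 400
        for _ in range(50):
            strands = [("+", "-")[int(rng.integers(2))] for _ in range(3)]
            ig = IntergenicRegion("ig1", "g1", "c1", 100, 300,
                                  left_gene=_flank(0, 100, strands[0]),
                                  right_gene=_flank(300, 400, strands[1]))
            orf = _orf("o1", ig, 150, 210, strands[2])
            rec = classify_orientation(orf, ig)
            flip = {"+": "-", "-": "+"}
            ig_rc = IntergenicRegion(
                "ig1", "g1", "c1", L - 300, L - 100,
                left_gene=FeatureRecord("c1", L - 400, L - 300,
                                        flip[strands[1]], "fr"),
                right_gene=FeatureRecord("c1", L - 100, L, flip[strands[0]], "fl"))
            orf_rc = _orf("o1", ig_rc, L - 210, L - 150, flip[strands[2]])
            rec_rc = classify_orientation(orf_rc, ig_rc)
            assert rec.upstream_relation == rec_rc.upstream_relation
            assert rec.downstream_relation == rec_rc.downstream_relation
            assert rec.dist_upstream == rec_rc.dist_upstream
            assert rec.dist_downstream == rec_rc.dist_downstream


def oracle_fisher(a, b, c, d):
    """Full hypergeometric enumeration with fixed margins."""
    from math import comb
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = comb(n, c1)
    def prob(k):
        if k < 0 or k > r1 or c1 - k < 0 or c1 - k > n - r1:
            return 0.0
        return comb(r1, k) * comb(n - r1, c1 - k) / denom
    p_obs = prob(a)
    total = 0.0
    for k in range(0, min(r1, c1) + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


class TestFisher:
    def test_balanced_table(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_diagonal_table(self):
        assert fisher_exact_2x2([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])

    def test_matches_enumeration_random_tables(self, rng):
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 11, size=4))
            assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
                oracle_fisher(a, b, c, d), rel=1e-7, abs=1e-12)


class TestEnrichment:
    def _records(self, n, collinear_down, rng=None, p=None):
        recs = []
        for i in range(n):
            if p is not None:
                down = "collinear" if rng.random() < p else "convergent"
            else:
                down = "collinear" if i < collinear_down else "convergent"
            recs.append(ContextRecord(f"o{i}", "+", "divergent", down,
                                      5, 5, False, False))
        return recs

    def test_extreme_enrichment_rejected_by_all_nulls(self):
        recs = self._records(100, 100)
        rep = orientation_enrichment(recs, seed=0)
        assert rep["downstream_collinear"]["binom_p"] < 1e-10
        assert rep["downstream_collinear"]["perm_p"] < 1e-3
        assert rep["downstream_collinear"]["fisher_p"] < 1e-10

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            orientation_enrichment(self._records(5, 5))

    def test_empty_relation_class_handled(self):
        recs = [ContextRecord(f"o{i}", "+", "none", "none", None, None,
                              False, False) for i in range(12)]
        rep = orientation_enrichment(recs, seed=0)
        assert rep["downstream_collinear"]["binom_p"] is None
        assert rep["head_to_tail_fraction"] is None
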