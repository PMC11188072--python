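import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from Bio.Seq import Seq

from ismorf.intergenic_orfs import (
    IsmOrf,
    complement_intervals,
    extract_intergenic,
    filter_known_protein_hits,
    find_orfs,
    select_ismorfs,
)
from ismorf.io_formats import GenomeSequence

from conftest import make_genome


class TestExtractIntergenic:
    def test_set_complement(self):
        g = make_genome("A" * 500, [(0, 100, "+"), (150, 400, "+")])
        igs = extract_intergenic(g, min_len=33, max_len=1500)
        assert [(ig.start, ig.end) for ig in igs] == [(100, 150), (400, 500)]
        assert igs[0].left_gene.feature_id == "g1_gene0"
        assert igs[0].right_gene.feature_id == "g1_gene1"
        assert igs[1].right_gene is None

    def test_adjacent_genes_leave_no_gap(self):
        g = make_genome("A" * 200, [(0, 100, "+"), (100, 200, "+")])
        assert extract_intergenic(g) == []

    def test_short_gap_filtered(self):
        g = make_genome("A" * 220, [(0, 100, "+"), (120, 220, "+")])
        assert extract_intergenic(g) == []  # 20 nt < 33

    def test_overlapping_genes_unioned(self):
        g = make_genome("A" * 300, [(0, 120, "+"), (80, 200, "-")])
        igs = extract_intergenic(g)
        assert [(ig.start, ig.end) for ig in igs] == [(200, 300)]

    def test_geneless_contig_is_one_candidate(self):
        g = make_genome("A" * 100, [])
        igs = extract_intergenic(g)
        assert [(ig.start, ig.end) for ig in igs] == [(0, 100)]
        assert extract_intergenic(make_genome("A" * 2000, [])) == []  # > 1500

    def test_circular_wraparound_joined(self):
        g = make_genome("A" * 300, [(50, 100, "+"), (150, 250, "+")],
                        circular=True)
        igs = extract_intergenic(g)
        spans = [(ig.start, ig.end) for ig in igs]
        assert (250, 350) in spans       # tail (250..300) + head (0..50)
        assert (100, 150) in spans

    def test_complementarity_tiles_contig(self, rng):
        # gene union + candidate gaps tile [0, L) exactly
        L = 1000
        genes = []
        pos = 0
        while pos < L - 50:
            s = pos + int(rng.integers(0, 60))
            e = min(L, s + int(rng.integers(10, 120)))
            if e > s:
                genes.append((s, e, "+"))
            pos = e + 1
        merged = []
        for s, e, _ in sorted(genes):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        gaps = complement_intervals([(s, e) for s, e in merged], L)
        covered = sorted([(s, e) for s, e in merged] + gaps)
        assert covered[0][0] == 0 and covered[-1][1] == L
        assert all(a[1] == b[0] for a, b in zip(covered, covered[1:]))


class TestFindOrfs:
    def test_simple_orf_translated(self):
        seq = GenomeSequence("c", "ATG" + "AAA" * 14 + "TAA")
        orfs = [o for o in find_orfs(seq) if o.strand == "+"]
        assert len(orfs) == 1
        assert orfs[0].protein == "M" + "K" * 14
        assert (orfs[0].start, orfs[0].end) == (0, 48)

    def test_alternative_starts_give_met(self):
        seq = GenomeSequence("c", "GTG" + "AAA" * 14 + "TAA")
        (orf,) = [o for o in find_orfs(seq) if o.strand == "+"]
        assert orf.start_codon == "GTG"
        assert orf.protein.startswith("M")

    def test_no_stop_no_orf(self):
        assert find_orfs(GenomeSequence("c", "ATG" + "AAA" * 20)) == []

    def test_min_length_boundary(self):
        # coding length 42 nt (14 codons) < 45 -> rejected
        seq = GenomeSequence("c", "ATG" + "AAA" * 13 + "TAA")
        assert [o for o in find_orfs(seq) if o.strand == "+"] == []

    def test_nested_starts_longest_by_default(self):
        inner = "ATG" + "AAA" * 20 + "ATGAAA" + "TAA"
        seq = GenomeSequence("c", inner)
        plus = [o for o in find_orfs(seq) if o.strand == "+"]
        assert len(plus) == 1 and plus[0].start == 0
        plus_all = [o for o in find_orfs(seq, min_nt=6, all_starts=True)
                    if o.strand == "+"]
        assert {o.start for o in plus_all} == {0, 63}

    def test_n_codon_breaks_scan(self):
        seq = GenomeSequence("c", "ATG" + "AAA" * 7 + "ANA" + "AAA" * 7 + "TAA")
        assert [o for o in find_orfs(seq, min_nt=9) if o.strand == "+"] == []

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=60, max_size=300))
    def test_reverse_complement_symmetry(self, s):
        fwd = find_orfs(GenomeSequence("c", s), min_nt=9)
        rev = find_orfs(GenomeSequence("c", str(Seq(s).reverse_complement())), min_nt=9)
        n = len(s)
        mirrored = sorted((n - o.end, n - o.start, {"+": "-", "-": "+"}[o.strand])
                          for o in rev)
        assert sorted((o.start, o.end, o.strand) for o in fwd) == mirrored


class TestSelectIsmorfs:
    def _orf(self, start, end, protein_len=None):
        from ismorf.intergenic_orfs import CandidateOrf
        n_aa = protein_len if protein_len is not None else (end - start) // 3 - 1
        return CandidateOrf("c1", start, end, "+", "ATG", "M" + "A" * (n_aa - 1))

    def _igs(self, spans):
        from ismorf.intergenic_orfs import IntergenicRegion
        return [IntergenicRegion(f"ig{i}", "g1", "c1", s, e)
                for i, (s, e) in enumerate(spans)]

    def test_full_containment_kept(self):
        out = select_ismorfs([self._orf(100, 160)], self._igs([(90, 300)]), "g1")
        assert len(out) == 1 and out[0].containment == 1.0

    def test_partial_overlap_dropped(self):
        assert select_ismorfs([self._orf(280, 340)], self._igs([(90, 300)]), "g1") == []

    def test_boundary_fraction_kept(self):
        # 48/60 = 0.8 exactly
        out = select_ismorfs([self._orf(100, 160)], self._igs([(100, 148)]), "g1")
        assert len(out) == 1 and out[0].containment == pytest.approx(0.8)

    def test_protein_length_window(self):
        short = self._orf(100, 148, protein_len=14)   # 14 aa
        assert select_ismorfs([short], self._igs([(90, 300)]), "g1") == []

    def test_multiple_igs_single_report(self):
        out = select_ismorfs([self._orf(100, 160)],
                             self._igs([(90, 300), (95, 299)]), "g1")
        assert len(out) == 1


class TestKnownHitFilter:
    def _ismorfs(self):
        return [IsmOrf("o1", "ig1", "g1", "c1", 0, 63, "+", "ATG",
                       "M" + "A" * 19, 1.0),
                IsmOrf("o2", "ig1", "g1", "c1", 100, 163, "+", "ATG",
                       "M" + "A" * 19, 1.0)]

    def test_joint_rule_removes(self):
        hits = pd.DataFrame([{"orf_id": "o1", "evalue": 1e-6,
                              "pct_identity": 60.0, "aln_len": 12}])
        kept, report = filter_known_protein_hits(self._ismorfs(), hits)
        assert [o.orf_id for o in kept] == ["o2"]
        assert list(report.orf_id) == ["o1"]

    def test_failing_evalue_retains(self):
        hits = pd.DataFrame([{"orf_id": "o1", "evalue": 1e-4,
                              "pct_identity": 90.0, "aln_len": 20}])
        kept, report = filter_known_protein_hits(self._ismorfs(), hits)
        assert len(kept) == 2 and report.empty

    def test_empty_table_is_identity(self):
        kept, report = filter_known_protein_hits(
            self._ismorfs(), pd.DataFrame(columns=["orf_id", "evalue",
                                                   "pct_identity", "aln_len"]))
        assert len(kept) == 2

    def test_unknown_orf_id_ignored(self):
        hits = pd.DataFrame([{"orf_id": "nope", "evalue": 1e-9,
                              "pct_identity": 99.0, "aln_len": 20}])
        kept, _ = filter_known_protein_hits(self._ismorfs(), hits)
        assert len(kept) == 2
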