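import itertools
import math
from collections import Counter

import numpy as np
import pytest

from ismorf.calibration_classify import (
    ThresholdSet,
    bootstrap_quantiles,
    build_shuffled_null,
    classify_thresholds,
    evaluate_agreement,
    klet_shuffle,
    train_rate_classifier,
)
from ismorf.codon_evolution import EvolScores, cluster_evolscores
from ismorf.simulator import simulate_cluster

from conftest import random_dna


def kmer_counts(s, k):
    return Counter(s[i:i + k] for i in range(len(s) - k + 1))


def valid_shuffles(s, k):
    """Brute-force set of distinct permutations with identical k-mer counts."""
    target = kmer_counts(s, k)
    return {"".join(p) for p in itertools.permutations(s)
            if kmer_counts("".join(p), k) == target}


class TestKletShuffle:
    def test_single_arrangement_fixed(self):
        assert klet_shuffle("AAAA", k=3, seed=1) == "AAAA"

    def test_kmer_counts_and_endpoints_preserved(self, rng):
        for _ in range(50):
            s = random_dna(rng, int(rng.integers(10, 120)))
            out = klet_shuffle(s, k=3, seed=rng)
            assert len(out) == len(s)
            for k in (1, 2, 3):
                assert kmer_counts(out, k) == kmer_counts(s, k)
            assert out[:2] == s[:2] and out[-2:] == s[-2:]

    def test_short_input_returned(self):
        assert klet_shuffle("AC", k=3, seed=0) == "AC"

    def test_k1_is_plain_permutation(self):
        out = klet_shuffle("AACGT", k=1, seed=3)
        assert sorted(out) == sorted("AACGT")

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            klet_shuffle("ACGT", k=0, seed=0)

    def test_outputs_within_valid_set(self):
        s = "ACGTACGT"
        valid = valid_shuffles(s, 3)
        seen = {klet_shuffle(s, k=3, seed=i) for i in range(200)}
        assert seen <= valid

    def test_determinism(self):
        s = "ACGTAGCTAGCATCGATCG"
        assert klet_shuffle(s, 3, seed=11) == klet_shuffle(s, 3, seed=11)


class TestShuffledNull:
    def _clusters(self, n, rng):
        out = []
        for i in range(n):
            cl, _ = simulate_cluster(4, 40, omega=0.1, branch_scale=0.1,
                                     seed=rng, cluster_id=f"c{i}")
            out.append(cl)
        return out

    def test_composition_preserved(self, rng):
        (cl,) = self._clusters(1, rng)
        (null,) = build_shuffled_null([cl], seed=5)
        for mid in cl.member_ids:
            assert len(null.cds[mid]) == len(cl.cds[mid])
            for k in (1, 2, 3):
                assert kmer_counts(null.cds[mid], k) == kmer_counts(cl.cds[mid], k)

    def test_same_seed_identical_corpus(self, rng):
        clusters = self._clusters(3, rng)
        a = build_shuffled_null(clusters, seed=9)
        b = build_shuffled_null(clusters, seed=9)
        assert [c.cds for c in a] == [c.cds for c in b]

    def test_null_scores_stochastically_larger(self, rng):
        from scipy.stats import mannwhitneyu
        clusters = self._clusters(40, rng)
        nulls = build_shuffled_null(clusters, seed=1)
        real_kd = [cluster_evolscores(c).Kd for c in clusters]
        null_kd = [min(cluster_evolscores(c).Kd, 10.0) for c in nulls]
        p = mannwhitneyu(null_kd, real_kd, alternative="greater").pvalue
        assert p < 0.01


class TestBootstrapQuantiles:
    def test_constant_values(self):
        rep = bootstrap_quantiles([0.3] * 100, seed=1)
        assert rep.q_low == pytest.approx(0.3, abs=1e-12)
        assert rep.q_high == pytest.approx(0.3, abs=1e-12)
        assert rep.q_low_spread == pytest.approx((0.3, 0.3), abs=1e-12)

    def test_uniform_q99_closed_form(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 1, size=10000).tolist()
        rep = bootstrap_quantiles(vals, seed=2, B=200)
        assert rep.q_high == pytest.approx(0.99, abs=0.01)
        assert rep.q_low == pytest.approx(0.01, abs=0.01)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_quantiles([0.5] * 19, seed=0)

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_quantiles([0.5] * 100, B=0, seed=0)


def _scores(dn, ds, kd, dnds):
    return EvolScores("x", dn, ds, kd, dnds, 3, 3)


class TestClassifyThresholds:
    @pytest.mark.parametrize("vals,expected", [
        ((0.1, 0.5, 0.15, 0.2), "coding"),
        ((0.25, 0.5, 0.15, 0.2), "noncoding"),   # dN bound violated
        ((0.1, 0.8, 0.15, 0.2), "noncoding"),
        ((0.1, 0.5, 0.25, 0.2), "noncoding"),
        ((0.1, 0.5, 0.15, 0.6), "noncoding"),
        ((0.2, 0.7, 0.2, 0.5), "noncoding"),     # boundary is strict
    ])
    def test_threshold_rule(self, vals, expected):
        assert classify_thresholds(_scores(*vals)) == expected

    def test_nonfinite_is_noncoding(self):
        assert classify_thresholds(_scores(0.1, 0.5, 0.1, math.inf)) == "noncoding"

    def test_monotone_in_each_statistic(self, rng):
        for _ in range(200):
            vals = rng.uniform(0, 1.0, size=4)
            base = classify_thresholds(_scores(*vals))
            k = int(rng.integers(4))
            worse = vals.copy()
            worse[k] += rng.uniform(0, 1.0)
            worsened = classify_thresholds(_scores(*worse))
            if base == "noncoding":
                assert worsened == "noncoding"

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSet(dn_max=0.0)


class TestRateClassifier:
    def test_separable_classes_perfect_auroc(self):
        pos = [_scores(0.05, 0.3, 0.05, 0.2) for _ in range(100)]
        neg = [_scores(1.5, 2.0, 1.8, 3.0) for _ in range(100)]
        _, metrics = train_rate_classifier(pos, neg, seed=0)
        assert metrics["auroc"] == 1.0
        assert metrics["precision"] == 1.0 and metrics["recall"] == 1.0

    def test_no_signal_auroc_near_half(self):
        rng = np.random.default_rng(3)
        def draw():
            return _scores(*rng.uniform(0, 1, size=4))
        pos = [draw() for _ in range(250)]
        neg = [draw() for _ in range(250)]
        _, metrics = train_rate_classifier(pos, neg, seed=0)
        assert abs(metrics["auroc"] - 0.5) <= 0.1

    def test_small_class_rejected(self):
        pos = [_scores(0.1, 0.1, 0.1, 0.1)] * 5
        neg = [_scores(1, 1, 1, 1)] * 100
        with pytest.raises(ValueError):
            train_rate_classifier(pos, neg)

    def test_nonfinite_features_encoded(self):
        pos = [_scores(0.05, 0.3, 0.05, 0.2) for _ in range(50)]
        neg = [_scores(1.5, 2.0, 1.8, math.inf) for _ in range(50)]
        clf, metrics = train_rate_classifier(pos, neg, seed=0)
        assert metrics["auroc"] == 1.0
        assert clf.predict([_scores(1.5, 2.0, 1.8, math.inf)]) == ["noncoding"]


class TestAgreement:
    def test_identical_labelings(self):
        labels = {f"c{i}": ("coding" if i % 2 else "noncoding") for i in range(10)}
        overlap, conf = evaluate_agreement(labels, dict(labels))
        assert overlap == 1.0 and conf["only_a"] == conf["only_b"] == 0

    def test_one_disagreement_among_100(self):
        a = {f"c{i}": "coding" for i in range(100)}
        b = dict(a)
        b["c0"] = "noncoding"
        extra = {"c100": "coding"}
        a.update({"c100": "noncoding"})
        b.update(extra)
        overlap, _ = evaluate_agreement(a, b)
        assert overlap == pytest.approx(99 / 101)

    def test_empty_coding_sets_agree(self):
        a = {"c1": "noncoding"}
        overlap, _ = evaluate_agreement(a, dict(a))
        assert overlap == 1.0

    def test_different_universes_rejected(self):
        with pytest.raises(ValueError):
            evaluate_agreement({"a": "coding"}, {"b": "coding"})
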