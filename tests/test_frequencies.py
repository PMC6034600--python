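"""Allele counting, sex-aware pooling, and male/female homogeneity testing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xstrkit.frequencies import (
    build_frequency_table,
    count_alleles,
    pool_frequencies,
    sex_homogeneity_test,
)
from xstrkit.genotypes import AlleleLabel
from xstrkit.simulate import SimSpec, simulate_table

from conftest import make_table


def A(text):
    return AlleleLabel.parse(text)


class TestCountAlleles:
    def test_males_one_chromosome_females_two(self):
        table = make_table(
            [
                ("m1", "male", {"LOC": "10"}),
                ("m2", "male", {"LOC": "10"}),
                ("f1", "female", {"LOC": "10/25.1"}),
            ],
            ["LOC"],
        )
        cm, cf = count_alleles(table, "LOC")
        assert dict(cm) == {A("10"): 2}
        assert dict(cf) == {A("10"): 1, A("25.1"): 1}

    def test_all_missing_warns_and_returns_empty(self):
        table = make_table(
            [("m1", "male", {"LOC": None}), ("f1", "female", {"LOC": None})],
            ["LOC"],
        )
        with pytest.warns(UserWarning, match="no calls"):
            cm, cf = count_alleles(table, "LOC")
        assert not cm and not cf

    def test_unknown_locus_raises(self, toy_table):
        with pytest.raises(KeyError):
            count_alleles(toy_table, "NOPE")


class TestPooling:
    def test_equal_vectors_are_a_fixed_point(self):
        v = {"A": 0.3, "B": 0.7}
        assert pool_frequencies(v, v, "paper") == pytest.approx(v)
        assert pool_frequencies(v, v, "chromosome-weighted",
                                n_female=111, n_male=156) == pytest.approx(v)

    def test_disjoint_support_weights_two_to_one(self):
        pooled = pool_frequencies({"A": 1.0}, {"B": 1.0}, "paper")
        assert pooled == pytest.approx({"A": 2 / 3, "B": 1 / 3})

    def test_hand_arithmetic(self):
        pooled = pool_frequencies(
            {"A": 0.4, "B": 0.6}, {"A": 0.7, "B": 0.3}, "paper"
        )
        assert pooled == pytest.approx({"A": 0.5, "B": 0.5})

    def test_rejects_non_probability_vector(self):
        with pytest.raises(ValueError, match="sum"):
            pool_frequencies({"A": 0.5}, {"A": 1.0})

    def test_rejects_unknown_method(self):
        with pytest.raises(ValueError, match="method"):
            pool_frequencies({"A": 1.0}, {"A": 1.0}, method="mean")

    @given(
        pf=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
        pm=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
    )
    @settings(derandomize=True, max_examples=50)
    def test_pooled_lies_between_strata_and_sums_to_one(self, pf, pm):
        k = min(len(pf), len(pm))
        pf = {i: v / sum(pf[:k]) for i, v in enumerate(pf[:k])}
        pm = {i: v / sum(pm[:k]) for i, v in enumerate(pm[:k])}
        pooled = pool_frequencies(pf, pm, "paper")
        assert sum(pooled.values()) == pytest.approx(1.0, abs=1e-9)
        for a, p in pooled.items():
            lo, hi = sorted((pf.get(a, 0.0), pm.get(a, 0.0)))
            assert lo - 1e-12 <= p <= hi + 1e-12

    @given(pf=st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
           pm=st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
           n=st.integers(1, 500))
    @settings(derandomize=True, max_examples=30)
    def test_paper_weights_equal_chromosome_weights_at_equal_sample_sizes(
        self, pf, pm, n
    ):
        pf = {i: v / sum(pf) for i, v in enumerate(pf)}
        pm = {i: v / sum(pm) for i, v in enumerate(pm)}
        a = pool_frequencies(pf, pm, "paper")
        b = pool_frequencies(pf, pm, "chromosome-weighted", n_female=n, n_male=n)
        assert a == pytest.approx(b, abs=1e-12)


class TestSexHomogeneity:
    def test_proportional_counts_give_p_one(self):
        p = sex_homogeneity_test(
            {"A": 10, "B": 30}, {"A": 25, "B": 75}, n_reps=500, seed=0
        )
        assert p == 1.0  # G = 0: every permutation is at least as extreme

    def test_complete_separation_is_detected(self):
        p = sex_homogeneity_test({"A": 50}, {"B": 100}, n_reps=10_000, seed=0)
        assert p < 0.01

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="n_reps"):
            sex_homogeneity_test({"A": 5}, {"A": 5}, n_reps=50)

    def test_type_one_error_calibrated_under_shared_frequencies(self, rng):
        # both strata drawn from one vector: ~5% rejections at alpha=0.05
        p_truth = np.array([0.4, 0.3, 0.2, 0.1])
        rejections = 0
        n_loci = 300
        for i in range(n_loci):
            m = rng.multinomial(120, p_truth)
            f = rng.multinomial(200, p_truth)
            cm = {a: int(c) for a, c in enumerate(m) if c}
            cf = {a: int(c) for a, c in enumerate(f) if c}
            p = sex_homogeneity_test(cm, cf, n_reps=400, seed=int(rng.integers(2**31)))
            rejections += p <= 0.05
        assert abs(rejections / n_loci - 0.05) < 0.03


class TestFrequencyTable:
    def test_estimates_converge_to_generator_truth(self):
        # 2000 chromosomes per locus: max |p_hat - p| within binomial bounds
        spec = SimSpec(n_loci=3, n_males=1000, n_females=500)
        table, truth = simulate_table(spec, 11)
        # chromosome weighting makes p_hat the straight MLE over 2000 chromosomes
        ft = build_frequency_table(table, pooling="chromosome-weighted")
        n_chrom = 2000
        for locus in table.loci:
            for a, p in truth[locus].items():
                p_hat = ft.freq_pooled[locus].get(a, 0.0)
                bound = 3 * np.sqrt(p * (1 - p) / n_chrom) + 1 / n_chrom
                assert abs(p_hat - p) < bound, (locus, str(a))

    def test_pooled_vectors_sum_to_one(self):
        spec = SimSpec(n_loci=4, n_males=40, n_females=30, missing_rate=0.1)
        table, _ = simulate_table(spec, 2)
        ft = build_frequency_table(table)
        for locus in table.loci:
            assert sum(ft.freq_pooled[locus].values()) == pytest.approx(1.0, abs=1e-9)
            assert sum(ft.counts_male[locus].values()) == ft.n_male[locus]
            assert sum(ft.counts_female[locus].values()) == 2 * ft.n_female[locus]

    def test_tsv_report_shape(self, tmp_path):
        spec = SimSpec(n_loci=2, n_males=10, n_females=10)
        table, _ = simulate_table(spec, 3)
        ft = build_frequency_table(table)
        out = tmp_path / "freq.tsv"
        ft.write_tsv(out)
        header = out.read_text().splitlines()[0].split("\t")
        assert header == [
            "locus", "allele", "count_m", "count_f",
            "freq_m", "freq_f", "freq_pooled",
        ]
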