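"""Diversity estimators, the 4x decision rule, and the delimitation traversal."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ktheta import (
    Alignment,
    DelimitConfig,
    KThetaDelimiter,
    TwoSpeciesModel,
    between_clade_K,
    classify_pair,
    delimit,
    diversity_estimate,
    mean_pairwise_within,
    pi_floor_zero,
    pi_hat,
    ratio_test,
    simulate_two_species_alignment,
    theta_hat,
)
from ktheta.core import DISTINCT, INDETERMINATE, SINGLE


class TestWithinCladeEstimators:
    def test_mean_pairwise_hand_example(self):
        aln = Alignment.from_sequences([("a", "AAAA"), ("b", "AAAT"), ("c", "AAAA")])
        assert mean_pairwise_within(aln, ["a", "b", "c"]) == pytest.approx(1 / 6)

    def test_identical_clade_is_zero(self):
        aln = Alignment.from_sequences([("a", "ACGT"), ("b", "ACGT"), ("c", "TTTT")])
        assert mean_pairwise_within(aln, ["a", "b"]) == 0.0

    def test_single_difference_over_258_sites(self):
        s = "A" * 258
        t = "A" * 257 + "C"
        aln = Alignment.from_sequences([("a", s), ("b", t)])
        assert mean_pairwise_within(aln, ["a", "b"]) == pytest.approx(0.003876, abs=1e-6)

    def test_singleton_returns_none(self):
        aln = Alignment.from_sequences([("a", "ACGT"), ("b", "ACGT")])
        assert mean_pairwise_within(aln, ["a"]) is None

    @pytest.mark.parametrize(
        "d_bar, n, expected",
        [
            (0.0076, 8, 0.008686),  # published raven figure, rounds to 0.0087
            (0.002, 17, 0.002125),  # rounds to 0.0021
            (0.0, 11, 0.0),
        ],
    )
    def test_pi_hat(self, d_bar, n, expected):
        assert pi_hat(d_bar, n) == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize(
        "L, n, expected",
        [(258, 3, 2 / 1548), (564, 2, 2 / 1128), (100, 2, 1 / 100)],
    )
    def test_pi_floor_zero(self, L, n, expected):
        assert pi_floor_zero(L, n) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "pi, expected",
        [(0.008686, 0.008787), (0.0, 0.0), (0.3, 0.5)],
    )
    def test_theta_hat(self, pi, expected):
        assert theta_hat(pi) == pytest.approx(expected, abs=1e-6)

    def test_theta_domain_error(self):
        with pytest.raises(ValueError):
            theta_hat(0.75)

    @given(
        st.floats(min_value=1e-6, max_value=0.3),
        st.integers(min_value=2, max_value=100),
    )
    def test_theta_ge_pi_ge_dbar(self, d_bar, n):
        pi = pi_hat(d_bar, n)
        theta = theta_hat(pi)
        assert theta > pi > d_bar

    def test_diversity_estimate_applies_zero_floor(self):
        aln = Alignment.from_sequences([("a", "A" * 50), ("b", "A" * 50), ("c", "T" * 50)])
        est = diversity_estimate(aln, ["a", "b"])
        assert est.zero_d and est.pi == pytest.approx(2 / (50 * 2 * 1))


class TestBetweenCladeDivergence:
    def test_hand_example_with_jc_correction(self):
        aln = Alignment.from_sequences(
            [("a1", "AAAA"), ("a2", "AAAA"), ("b1", "TTAA"), ("b2", "TTAA")]
        )
        D, K = between_clade_K(aln, ["a1", "a2"], ["b1", "b2"], "jc69")
        assert D == 0.5
        assert K == pytest.approx(0.823959, abs=1e-6)  # -0.75*ln(1/3)

    def test_identical_clones_are_zero(self):
        aln = Alignment.from_sequences([("a", "ACGT"), ("b", "ACGT"), ("c", "ACGT")])
        D, K = between_clade_K(aln, ["a"], ["b", "c"], "k2p")
        assert D == K == 0.0

    def test_correction_never_below_uncorrected(self, rng):
        aln, truth = simulate_two_species_alignment(
            TwoSpeciesModel(tau=4.0, n1=4, n2=4, theta_site=0.02, L=400), seed=3
        )
        sp1 = [i for i, s in truth.species.items() if s == 1]
        sp2 = [i for i, s in truth.species.items() if s == 2]
        D, K = between_clade_K(aln, sp1, sp2, "jc69")
        assert K >= D

    def test_disjointness_enforced(self, tiny_alignment):
        with pytest.raises(ValueError):
            between_clade_K(tiny_alignment, ["s1", "s2"], ["s2"], "jc69")


class TestRatioAndClassification:
    def test_published_ratio_examples(self):
        theta = theta_hat(pi_hat(0.0076, 8))
        assert ratio_test(0.0206, theta, 0.0013) == pytest.approx(2.344, abs=2e-3)
        theta2 = theta_hat(pi_hat(0.002, 17))
        assert ratio_test(0.0349, theta2, 0.0013) == pytest.approx(16.38, abs=2e-2)

    def test_larger_theta_is_used(self):
        assert ratio_test(0.1, 0.01, 0.02) == pytest.approx(5.0)
        assert ratio_test(0.1, 0.02, 0.01) == pytest.approx(5.0)

    def test_zero_divergence_gives_zero(self):
        assert ratio_test(0.0, 0.01, None) == 0.0

    def test_both_thetas_absent_rejected(self):
        with pytest.raises(ValueError):
            ratio_test(0.1, 0.0, None)

    @pytest.mark.parametrize(
        "ratio, expected",
        [(16.4, DISTINCT), (2.3, SINGLE), (4.0, DISTINCT), (3.999, SINGLE)],
    )
    def test_four_x_rule_boundary_inclusive(self, ratio, expected):
        assert classify_pair(ratio) == expected

    @given(st.floats(min_value=1e-4, max_value=0.05), st.floats(min_value=2.0, max_value=40.0))
    def test_ratio_scale_consistency(self, d_bar, mult):
        # doubling every distance changes the ratio only through the theta
        # correction, a first-order-invariant effect bounded by ~5*pi
        n = 10
        D = mult * d_bar
        pi1 = pi_hat(d_bar, n)
        r1 = ratio_test(D, theta_hat(pi1), None)
        r2 = ratio_test(2 * D, theta_hat(pi_hat(2 * d_bar, n)), None)
        assert abs(r2 - r1) / r1 <= 5.0 * pi1


class _Fixture:
    """Shared simulated dataset helpers for delimitation tests."""

    @staticmethod
    def fit(aln, seed=11, **kwargs):
        kwargs.setdefault("bootstrap_replicates", 100)
        kwargs.setdefault("prm_reps", 300)
        return KThetaDelimiter(seed=seed, **kwargs).fit(aln)


class TestDelimit:
    def test_singleton_sister_to_five_member_clade_splits(self):
        # five closely related sequences plus one divergent singleton
        base = list("A" * 60)
        members = []
        for i in range(5):
            s = base.copy()
            s[i] = "C"  # one private difference each -> d_bar > 0
            members.append((f"m{i}", "".join(s)))
        far = "".join("T" if j < 24 else b for j, b in enumerate(base))
        aln = Alignment.from_sequences(members + [("lone", far)])
        est = _Fixture.fit(aln)
        assert est.n_species_ == 2
        split = [t for t in est.pair_tests_ if t.decision == DISTINCT]
        assert split and {split[0].n1, split[0].n2} == {1, 5}
        # theta had to come from the clade side
        assert split[0].theta_used == pytest.approx(
            max(t for t in (split[0].theta_a, split[0].theta_b) if t is not None)
        )

    def test_two_sister_singletons_are_indeterminate(self):
        # two close singletons vs a distant supported clade
        aln = Alignment.from_sequences(
            [
                ("x", "A" * 40 + "C" * 0 + "A" * 20),
                ("y", "A" * 39 + "C" + "A" * 20),
                ("p1", "T" * 30 + "A" * 29 + "C"),
                ("p2", "T" * 30 + "A" * 30),
                ("p3", "T" * 30 + "G" + "A" * 29),
            ]
        )
        est = _Fixture.fit(aln)
        first = est.pair_tests_[0]
        assert {first.n1, first.n2} == {1} and first.decision == INDETERMINATE

    def test_panmictic_sample_is_one_species(self):
        aln, _ = simulate_two_species_alignment(
            TwoSpeciesModel(tau=0.0, n1=4, n2=4, theta_site=0.01, L=1000), seed=300
        )
        est = _Fixture.fit(aln, seed=400)
        assert est.n_species_ == 1

    def test_deep_split_recovers_two_species(self):
        aln, truth = simulate_two_species_alignment(
            TwoSpeciesModel(tau=20.0, n1=8, n2=8, theta_site=0.005, L=1000), seed=101
        )
        est = _Fixture.fit(aln, seed=201)
        assert est.n_species_ == 2
        # the partition separates the true species
        labels = {i: est.assignments_[i] for i in aln.ids}
        sp1_labels = {labels[i] for i, s in truth.species.items() if s == 1}
        sp2_labels = {labels[i] for i, s in truth.species.items() if s == 2}
        assert sp1_labels.isdisjoint(sp2_labels)

    def test_delimit_is_deterministic(self):
        aln, _ = simulate_two_species_alignment(
            TwoSpeciesModel(tau=8.0, n1=5, n2=5, theta_site=0.01, L=800), seed=7
        )
        a = _Fixture.fit(aln, seed=55)
        b = _Fixture.fit(aln, seed=55)
        assert a.assignments_ == b.assignments_
        assert [t.ratio for t in a.pair_tests_] == [t.ratio for t in b.pair_tests_]
        assert a.supports_ == b.supports_

    def test_merging_monotonicity_on_simulated_merges(self):
        # pooling sister clades never drops pooled d-bar below the smaller
        # within-clade d-bar
        for seed in range(4):
            aln, truth = simulate_two_species_alignment(
                TwoSpeciesModel(tau=2.0, n1=6, n2=6, theta_site=0.01, L=800), seed=seed
            )
            sp1 = [i for i, s in truth.species.items() if s == 1]
            sp2 = [i for i, s in truth.species.items() if s == 2]
            d1 = mean_pairwise_within(aln, sp1)
            d2 = mean_pairwise_within(aln, sp2)
            pooled = mean_pairwise_within(aln, sp1 + sp2)
            assert pooled >= min(d1, d2) - 1e-12

    def test_report_rounding_convention(self):
        aln, _ = simulate_two_species_alignment(
            TwoSpeciesModel(tau=10.0, n1=5, n2=5, theta_site=0.01, L=800), seed=9
        )
        est = _Fixture.fit(aln, seed=10)
        report = est.pair_report()
        ratios = report["ratio"].dropna()
        assert all(r == round(r, 1) for r in ratios)
        assert all(p == round(p, 4) for p in report["pi_A"].dropna())
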