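"""Occupancy statistics: expected step distributions, pooling, chi-square,
mixture estimation and binomial error bars."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smstoich.stoichfit import (
    LabelingParams,
    StepDist,
    StepHistogram,
    binomial_error,
    chisq_gof,
    fit_occupancy_mixture,
    k_site_distribution,
    pool_classes,
    single_site_distribution,
    single_site_gof,
)


def brute_force_k_site(k, single, f_labeled, conditioned=True):
    """Independent oracle: explicit enumeration of all per-site outcomes."""
    outcomes = [(0, 1.0 - f_labeled)] + [(s, f_labeled * p)
                                         for s, p in single.probs.items()]
    totals = {}
    for combo in itertools.product(outcomes, repeat=k):
        s = sum(c for c, _ in combo)
        p = 1.0
        for _, q in combo:
            p *= q
        totals[s] = totals.get(s, 0.0) + p
    if conditioned:
        norm = 1.0 - totals.pop(0, 0.0)
        totals = {s: p / norm for s, p in totals.items()}
    return {s: p for s, p in totals.items() if p > 0}


class TestSingleSiteDistribution:
    @pytest.mark.parametrize(
        "n1, n2, expected",
        [
            (189, 33, {1: 0.85135, 2: 0.14865}),  # mCherry-U2AF35, -ATP
            (162, 39, {1: 0.80597, 2: 0.19403}),  # mEGFP-U2B'', -ATP
            (7, 0, {1: 1.0}),  # no dimers at all
        ],
    )
    def test_ratio_of_calibration_counts(self, n1, n2, expected):
        dist = single_site_distribution(n1, n2)
        assert dist.conditioned
        assert dist.probs == pytest.approx(expected, abs=1e-5)

    def test_rejects_empty_calibration(self):
        with pytest.raises(ValueError):
            single_site_distribution(0, 0)


class TestKSiteDistribution:
    def test_k1_returns_single_unchanged(self, u2af35_labeling):
        single = single_site_distribution(189, 33)
        for f in (0.3, 0.75, 1.0):
            d = k_site_distribution(1, single, f)
            assert d.probs == pytest.approx(single.probs, abs=1e-12)

    def test_two_forced_monomers(self):
        d = k_site_distribution(2, StepDist({1: 1.0}, conditioned=True), 1.0)
        assert d.probs == pytest.approx({2: 1.0})

    def test_double_occupancy_u2af65_worked_case(self):
        # two sites, 69% labeled, free-protein dimer counts 243:33
        single = single_site_distribution(243, 33)
        d = k_site_distribution(2, single, 0.69)
        assert d.probs == pytest.approx(
            {1: 0.41670, 2: 0.46489, 3: 0.11090, 4: 0.00753}, abs=1e-5
        )

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    @pytest.mark.parametrize("f", [0.49, 0.69, 0.75, 1.0])
    def test_matches_enumeration_oracle(self, k, f):
        single = single_site_distribution(189, 33)
        d = k_site_distribution(k, single, f)
        oracle = brute_force_k_site(k, single, f)
        assert set(d.probs) == set(oracle)
        for s in oracle:
            assert d.probs[s] == pytest.approx(oracle[s], abs=1e-12)

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_unconditioned_zero_mass_is_unlabeled_power(self, k):
        single = single_site_distribution(189, 33)
        f = 0.75
        d = k_site_distribution(k, single, f, conditioned=False)
        assert d.probs[0] == pytest.approx((1 - f) ** k, abs=1e-12)
        assert sum(d.probs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_rejects_k0_and_unconditioned_single(self):
        single = single_site_distribution(189, 33)
        with pytest.raises(ValueError):
            k_site_distribution(0, single, 0.75)
        uncond = k_site_distribution(1, single, 0.75, conditioned=False)
        with pytest.raises(ValueError):
            k_site_distribution(2, uncond, 0.75)


class TestPoolClasses:
    def test_both_classes_large_unchanged(self):
        dist = single_site_distribution(189, 33)
        obs, exp, bounds = pool_classes({1: 143, 2: 21}, dist, 164)
        assert obs.tolist() == [143, 21]
        assert exp == pytest.approx([139.62, 24.38], abs=0.01)
        assert bounds == [(1, 1), (2, 2)]

    def test_small_top_classes_merge_downward(self):
        dist = StepDist({1: 100 / 122.3, 2: 20 / 122.3, 3: 2 / 122.3,
                         4: 0.3 / 122.3}, conditioned=True)
        obs, exp, bounds = pool_classes({1: 100, 2: 20, 3: 1, 4: 1}, dist, 122.3)
        assert bounds == [(1, 1), (2, 4)]
        assert obs.tolist() == [100, 22]
        assert exp == pytest.approx([100, 22.3], abs=1e-9)

    def test_min_expected_zero_keeps_classes(self):
        dist = StepDist({1: 0.9, 2: 0.05, 3: 0.05}, conditioned=True)
        obs, exp, bounds = pool_classes({1: 9, 2: 1, 3: 0}, dist, 10,
                                        min_expected=0.0)
        assert len(bounds) == 3

    def test_error_when_one_class_remains(self):
        dist = StepDist({1: 0.99, 2: 0.01}, conditioned=True)
        with pytest.raises(ValueError):
            pool_classes({1: 5, 2: 0}, dist, 6)


class TestChisqGof:
    def test_u2af35_single_occupancy_worked_example(self, u2af35_labeling):
        # observed: 143 one-step + 21 two-step complexes of 164 scored
        g = single_site_gof({1: 143, 2: 21}, u2af35_labeling, sites=1)
        # hand Pearson: E = (139.62, 24.38), chi2 = 3.38^2/139.62 + 3.38^2/24.38
        assert g.statistic == pytest.approx(0.550, abs=0.002)
        assert g.df == 1
        assert g.pvalue == pytest.approx(0.458, abs=0.002)

    def test_u2af65_single_occupancy_rejected(self, u2af65_labeling):
        # 55 of 278 complexes bleaching in two steps rejects single occupancy
        g = single_site_gof({1: 223, 2: 55}, u2af65_labeling, sites=1)
        # hand Pearson: E = (244.76, 33.24), chi2 = 21.76^2 (1/E1 + 1/E2)
        assert g.statistic == pytest.approx(16.18, abs=0.02)
        assert g.pvalue == pytest.approx(5.8e-5, rel=0.05)
        assert g.pvalue < 1e-4

    def test_perfect_agreement_gives_zero(self):
        g = chisq_gof([80.0, 20.0], [80.0, 20.0])
        assert g.statistic == 0.0
        assert g.pvalue == 1.0

    def test_p_monotone_in_statistic(self):
        stats = [chisq_gof([100 + d, 20 - d], [100, 20]).pvalue
                 for d in (0, 2, 5, 10)]
        assert stats == sorted(stats, reverse=True)

    def test_mismatched_classes_error(self):
        with pytest.raises(ValueError):
            chisq_gof([1.0, 2.0], [1.0, 2.0, 3.0])


class TestOccupancyMixture:
    def test_exact_recovery_from_expected_counts(self, u2af35_labeling):
        single = single_site_distribution(189, 33)
        u1 = k_site_distribution(1, single, 0.75, conditioned=False)
        observed = {s: 400 * p for s, p in u1.probs.items() if s >= 1}
        fit = fit_occupancy_mixture(observed, single, 0.75, range(380, 421, 5))
        assert fit.pi == pytest.approx((0.0, 1.0, 0.0), abs=1e-12)
        assert fit.n_accessible == 400
        assert fit.chisq == pytest.approx(0.0, abs=1e-9)

    def test_exact_recovery_of_interior_grid_point(self):
        single = StepDist({1: 0.85, 2: 0.15}, conditioned=True)
        pi = (0.2, 0.5, 0.3)
        u1 = k_site_distribution(1, single, 0.75, conditioned=False)
        u2 = k_site_distribution(2, single, 0.75, conditioned=False)
        n = 400
        observed = {}
        for s in range(1, 5):
            observed[s] = n * (pi[1] * u1.probs.get(s, 0) + pi[2] * u2.probs.get(s, 0))
        fit = fit_occupancy_mixture(observed, single, 0.75, range(390, 411))
        assert fit.pi == pytest.approx(pi, abs=1e-12)
        assert fit.n_accessible == 400

    def test_all_invisible_means_unoccupied(self):
        single = single_site_distribution(189, 33)
        fit = fit_occupancy_mixture({}, single, 0.75, [50])
        assert fit.pi == pytest.approx((1.0, 0.0, 0.0))

    def test_empty_candidate_range_errors(self):
        single = single_site_distribution(189, 33)
        with pytest.raises(ValueError):
            fit_occupancy_mixture({1: 10}, single, 0.75, [])


class TestBinomialError:
    def test_worked_values(self):
        assert binomial_error(50, 100) == pytest.approx(0.05)
        assert binomial_error(0, 17) == 0.0
        # 21 two-step complexes of 164: sqrt(p(1-p)/n) with p = 21/164
        assert binomial_error(21, 164) == pytest.approx(0.0261, abs=2e-4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(1, 500), st.data())
    def test_symmetric_under_complement(self, n, data):
        c = data.draw(st.integers(0, n))
        assert binomial_error(c, n) == pytest.approx(binomial_error(n - c, n))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            binomial_error(1, 0)
        with pytest.raises(ValueError):
            binomial_error(5, 4)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.integers(1, 4),
    st.floats(0.05, 1.0),
    st.integers(1, 400),
    st.integers(0, 400),
)
def test_k_site_distribution_always_normalized(k, f, n1, n2):
    single = single_site_distribution(n1, n2)
    d = k_site_distribution(k, single, f)
    assert sum(d.probs.values()) == pytest.approx(1.0, abs=1e-12)
    assert 0 not in d.probs


def test_step_histogram_invariants():
    h = StepHistogram(counts={1: 143, 2: 21}, nd_count=6, total_rna=850)
    assert h.total_scored == 164
    assert h.total_colocalized == 170
    assert h.colocalized_fraction == pytest.approx(0.2, abs=1e-12)
    with pytest.raises(ValueError):
        StepHistogram(counts={1: -1})
    with pytest.raises(ValueError):
        StepHistogram(counts={1: 10}, total_rna=5)


def test_labeling_params_dimer_fraction():
    lab = LabelingParams(0.75, 189, 33)
    assert lab.dimer_fraction == pytest.approx(33 / 222)
    with pytest.raises(ValueError):
        LabelingParams(1.5, 1, 1)
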