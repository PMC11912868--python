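"""PRF likelihoods, estimation, and information diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

from selage.errors import ValidationError
from selage.inference import (SelectionLikelihood, fisher_information,
                              fit_gamma, loglik_branch_averaged,
                              loglik_frequency, loglik_frequency_age,
                              read_sites, variance_ratio, write_sites)
from selage.popmodel import constant_model


@pytest.fixture(scope="module")
def small_lik():
    # 2n=30 resolves |gamma| up to ~10 cleanly (frequency threshold
    # 1/(2|gamma|) stays above the sample resolution zone)
    N, n = 1000, 15
    tpl = constant_model(n=n, N=N, s=0.0, mu=0.5, Tmax=2500)
    return SelectionLikelihood(tpl)


def _sites(i, a=None, lo=None, hi=None):
    df = pd.DataFrame({"site_id": np.arange(len(i)), "derived_count": i})
    if a is not None:
        df["age_gen"] = a
    if lo is not None:
        df["branch_lower_gen"] = lo
        df["branch_upper_gen"] = hi
    return df


class TestFrequencyLoglik:
    def test_empty_counts_give_minus_total_mean(self, small_lik):
        lam = small_lik.phi0(0.0)
        assert loglik_frequency(np.zeros_like(lam), lam) == pytest.approx(-lam.sum())

    def test_matches_scipy_poisson_sum(self, small_lik):
        rng = np.random.default_rng(3)
        lam = small_lik.phi0(-0.001)
        X = rng.poisson(lam)
        expected = poisson.logpmf(X, lam).sum()
        assert loglik_frequency(X, lam) == pytest.approx(expected, rel=1e-12)

    def test_zero_mean_with_observation_is_minus_inf(self):
        assert loglik_frequency(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == -np.inf

    def test_likelihood_prefers_generating_gamma(self, small_lik):
        rng = np.random.default_rng(11)
        lam_true = small_lik.phi0(-0.002)   # gamma = -4
        lam_wrong = small_lik.phi0(-0.005)  # gamma = -10
        wins = 0
        for _ in range(50):
            X = rng.poisson(lam_true)
            if loglik_frequency(X, lam_true) > loglik_frequency(X, lam_wrong):
                wins += 1
        assert wins > 40

    def test_profile_theta_removes_scale_information(self, small_lik):
        lam = small_lik.phi0(0.0)
        X = np.round(lam * 3.7)
        free = loglik_frequency(X, lam, profile_theta=True)
        scaled = loglik_frequency(X, 3.7 * lam, profile_theta=True)
        assert free == pytest.approx(scaled, rel=1e-12)


class TestFrequencyAgeLoglik:
    def test_cells_and_split_forms_identical(self, small_lik):
        rng = np.random.default_rng(5)
        lam = small_lik.phi0(-0.002)
        cond = small_lik.conditional_ages(-0.002)
        i = rng.integers(1, 16, size=40)
        a = rng.integers(1, 500, size=40)
        sites = _sites(i, a)
        l1 = loglik_frequency_age(sites, lam, cond, form="split")
        l2 = loglik_frequency_age(sites, lam, cond, form="cells")
        assert l1 == pytest.approx(l2, abs=1e-10)

    def test_single_site_decomposes(self, small_lik):
        lam = small_lik.phi0(0.0)
        cond = small_lik.conditional_ages(0.0)
        sites = _sites([3], [50])
        X = np.zeros_like(lam)
        X[2] = 1
        expected = loglik_frequency(X, lam) + np.log(cond[49, 2])
        assert loglik_frequency_age(sites, lam, cond) == pytest.approx(expected, rel=1e-12)

    def test_three_site_brute_force_over_joint_matrix(self, small_lik):
        """Direct evaluation oracle: independent Poisson cells over the
        joint (frequency, age) expected-count matrix."""
        lam = small_lik.phi0(-0.001)
        cond = small_lik.conditional_ages(-0.001)
        joint = lam[None, :] * cond  # expected counts per (a, i) cell
        sites = _sites([1, 1, 5], [3, 3, 120])
        brute = -joint.sum()
        brute += np.log(joint[2, 0] ** 2 / 2) + np.log(joint[119, 4])
        assert loglik_frequency_age(sites, lam, cond, form="cells") == \
            pytest.approx(brute, rel=1e-10)

    def test_age_out_of_range_rejected(self, small_lik):
        lam = small_lik.phi0(0.0)
        cond = small_lik.conditional_ages(0.0)
        with pytest.raises(ValidationError):
            loglik_frequency_age(_sites([1], [cond.shape[0] + 1]), lam, cond)


class TestBranchAveragedLoglik:
    def test_degenerate_interval_equals_exact_age(self, small_lik):
        lam = small_lik.phi0(-0.002)
        cond = small_lik.conditional_ages(-0.002)
        i, a = [2, 7, 1], [40, 200, 5]
        exact = loglik_frequency_age(_sites(i, a), lam, cond)
        branch = loglik_branch_averaged(_sites(i, lo=a, hi=a), lam, cond)
        assert branch == pytest.approx(exact, rel=1e-12)

    def test_average_bounded_by_extremes(self, small_lik):
        lam = small_lik.phi0(-0.002)
        cond = small_lik.conditional_ages(-0.002)
        lo, hi, i = 10, 60, 4
        avg = loglik_branch_averaged(_sites([i], lo=[lo], hi=[hi]), lam, cond)
        lmin = loglik_frequency_age(_sites([i], [int(np.argmin(cond[lo - 1:hi, i - 1])) + lo]), lam, cond)
        lmax = loglik_frequency_age(_sites([i], [int(np.argmax(cond[lo - 1:hi, i - 1])) + lo]), lam, cond)
        assert lmin <= avg <= lmax

    def test_monte_carlo_converges_to_exact_grid(self, small_lik):
        lam = small_lik.phi0(-0.002)
        cond = small_lik.conditional_ages(-0.002)
        sites = _sites([3, 6], lo=[20, 100], hi=[90, 400])
        grid = loglik_branch_averaged(sites, lam, cond, mode="exact_grid")
        mc = loglik_branch_averaged(sites, lam, cond, mode="monte_carlo",
                                    D=20000, seed=9)
        assert mc == pytest.approx(grid, abs=0.05)

    def test_monte_carlo_requires_seed(self, small_lik):
        lam = small_lik.phi0(0.0)
        cond = small_lik.conditional_ages(0.0)
        with pytest.raises(ValidationError):
            loglik_branch_averaged(_sites([1], lo=[1], hi=[5]), lam, cond,
                                   mode="monte_carlo")

    def test_empty_interval_rejected(self, small_lik):
        lam = small_lik.phi0(0.0)
        cond = small_lik.conditional_ages(0.0)
        with pytest.raises(ValidationError):
            loglik_branch_averaged(_sites([1], lo=[10], hi=[5]), lam, cond)


class TestFitGamma:
    def test_noise_free_self_consistency(self, small_lik):
        """Fitting the expected spectrum itself recovers the generating
        coefficient within 1%."""
        s_true = -0.0025
        lam = small_lik.phi0(s_true)
        X = lam.copy()  # expected counts as noise-free data
        from scipy.optimize import minimize_scalar
        res = minimize_scalar(lambda s: -loglik_frequency(X, small_lik.phi0(s)),
                              bounds=(-0.0075, 0.0075), method="bounded",
                              options={"xatol": 1e-8})
        assert abs(res.x / s_true - 1.0) < 0.01

    def test_empty_after_threshold_rejected(self, small_lik):
        sites = _sites([1, 1, 29])  # all at MAF 1/30, below the cutoff
        with pytest.raises(ValidationError):
            fit_gamma(sites, small_lik, mode="freq", maf_min=0.4)

    def test_unknown_mode_rejected(self, small_lik):
        with pytest.raises(ValidationError):
            fit_gamma(_sites([1]), small_lik, mode="bayes")

    def test_bound_landing_flagged(self, small_lik):
        # data overwhelmingly favouring strong negative selection, bounds
        # too narrow to reach it
        sites = _sites([1] * 200 + [2] * 5)
        res = fit_gamma(sites, small_lik, mode="freq", bounds=(-0.001, 0.001),
                        profile_theta=True)
        assert res.at_bound


class TestFisherInformation:
    def test_info_ratio_at_least_one(self, small_lik):
        for gam in (-10.0, -3.0, 3.0, 10.0):
            s = fisher_information(small_lik, gam)
            assert s.info_ratio >= 1.0

    def test_step_refinement_stable(self, small_lik):
        a = fisher_information(small_lik, -5.0, rel_step=1e-3)
        b = fisher_information(small_lik, -5.0, rel_step=5e-4)
        assert a.I_freq == pytest.approx(b.I_freq, rel=0.01)
        assert a.I_freq_age == pytest.approx(b.I_freq_age, rel=0.01)

    def test_threshold_raises_information_gain(self, small_lik):
        full = fisher_information(small_lik, -10.0)
        thresh = fisher_information(small_lik, -10.0, maf_min=0.125)
        assert thresh.info_ratio > full.info_ratio


class TestVarianceRatio:
    def test_identical_lists_give_one(self):
        assert variance_ratio([1.0, 2, 3], [1.0, 2, 3]) == pytest.approx(1.0)

    def test_positive(self):
        assert variance_ratio([0.0, 1, 5], [1.0, 1.2, 0.9]) > 0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValidationError):
            variance_ratio([1.0, 2.0], [3.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            variance_ratio([1.0, 2.0], [1.0])


class TestSiteTableIO:
    def test_round_trip_with_provenance_header(self, tmp_path):
        df = _sites([1, 4, 9], [10, 20, 30])
        p = tmp_path / "sites.tsv"
        write_sites(df, p, header_comment="config: {}")
        back = read_sites(p)
        pd.testing.assert_frame_equal(back, df)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("a\tb\n1\t2\n")
        with pytest.raises(ValidationError):
            read_sites(p)
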