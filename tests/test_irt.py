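import numpy as np
import pytest

from scalestep import (
    GRMFit,
    GeneratorConfig,
    fit_grm,
    fit_rsm,
    generate_grm,
    generate_rsm,
    grm_category_probs,
    item_information,
    lr_test_equal_discrimination,
    relative_information,
    score_persons,
)
from scalestep.exceptions import PreconditionError
from conftest import make_matrix


SUMZERO_T = np.array([-1.05, -0.35, 0.35, 1.05])


@pytest.fixture(scope="module")
def grm_fit_pair():
    """Free- and equal-discrimination fits of one mixed-slope dataset."""
    cfg = GeneratorConfig(
        n_persons=600, a=np.linspace(0.6, 2.2, 6), b=np.linspace(-1, 1.2, 6),
        t=np.array([-0.9, 0.0, 0.9]), seed=21,
    )
    R, truth = generate_grm(cfg)
    free = fit_grm(R, "common", "free", n_quadrature=21, compute_se=False)
    equal = fit_grm(R, "common", "equal", n_quadrature=21, compute_se=False)
    return R, truth, free, equal


class TestRSM:
    def test_parameter_recovery(self):
        cfg = GeneratorConfig(
            n_persons=1000, beta=np.linspace(-1, 1.5, 9),
            tau=np.array([-0.9, 0.1, 0.8]), latent_sd=1.3, seed=11,
        )
        R, truth = generate_rsm(cfg)
        fit = fit_rsm(R)
        assert fit.converged
        assert np.corrcoef(truth["beta"], fit.beta)[0, 1] >= 0.95
        assert np.abs(truth["beta"] - fit.beta).mean() <= 0.15
        assert fit.latent_sd == pytest.approx(1.3, abs=0.15)
        assert fit.tau.sum() == pytest.approx(0.0, abs=1e-10)

    def test_em_loglik_monotone(self):
        cfg = GeneratorConfig(
            n_persons=200, beta=np.linspace(-0.5, 1, 5),
            tau=np.array([-0.7, 0.7]), seed=3,
        )
        R, _ = generate_rsm(cfg)
        fit = fit_rsm(R)
        assert np.all(np.diff(fit.ll_history) >= -1e-8)

    def test_column_permutation_equivariance(self):
        cfg = GeneratorConfig(
            n_persons=300, beta=np.linspace(-1, 1, 6), tau=np.array([-0.7, 0.7]), seed=5,
        )
        R, _ = generate_rsm(cfg)
        fit = fit_rsm(R)
        perm = [3, 0, 5, 1, 4, 2]
        Rp = R.select_items(perm)
        fitp = fit_rsm(Rp)
        assert fitp.loglik == pytest.approx(fit.loglik, abs=1e-3)
        np.testing.assert_allclose(fitp.beta, fit.beta[perm], atol=1e-3)

    def test_identical_patterns_identical_scores(self):
        vals = np.array([[0, 1, 2], [0, 1, 2], [2, 2, 1], [1, 0, 0], [2, 1, 2]])
        R = make_matrix(vals, n_categories=[3] * 3)
        fit = fit_rsm(R)
        scores = score_persons(fit, R)
        assert scores.theta[0] == pytest.approx(scores.theta[1], abs=1e-12)

    def test_unequal_categories_rejected(self):
        R = make_matrix(np.array([[0, 1], [1, 2], [1, 0]]), n_categories=[2, 3])
        with pytest.raises(PreconditionError):
            fit_rsm(R)

    def test_sum_score_sufficiency(self):
        cfg = GeneratorConfig(
            n_persons=400, beta=np.linspace(-1, 1.5, 7),
            tau=np.array([-0.8, 0.0, 0.8]), seed=13,
        )
        R, _ = generate_rsm(cfg)
        fit = fit_rsm(R)
        scores = score_persons(fit, R)
        sums = R.values.sum(axis=1)
        # EAP must be a strictly increasing function of the raw sum score
        order = np.argsort(sums, kind="stable")
        by_sum = {}
        for p in order:
            by_sum.setdefault(sums[p], []).append(scores.theta[p])
        levels = sorted(by_sum)
        for s in levels:
            assert np.ptp(by_sum[s]) < 1e-10
        means = [np.mean(by_sum[s]) for s in levels]
        assert np.all(np.diff(means) > 0)


class TestGRM:
    def test_parameter_recovery(self, grm_data_1000):
        R, truth = grm_data_1000
        fit = fit_grm(R, "common", "free", compute_se=False)
        assert np.corrcoef(truth["a"], fit.a)[0, 1] >= 0.95
        assert np.corrcoef(truth["b"], fit.b)[0, 1] >= 0.95
        assert fit.converged

    def test_em_loglik_monotone(self, grm_fit_pair):
        _, _, free, equal = grm_fit_pair
        for fit in (free, equal):
            assert np.all(np.diff(fit.ll_history) >= -1e-8)

    def test_nesting_chain(self, grm_fit_pair):
        R, _, free, equal = grm_fit_pair
        free_t = fit_grm(R, "free", "free", n_quadrature=21, compute_se=False)
        assert equal.loglik <= free.loglik + 1e-6
        assert free.loglik <= free_t.loglik + 1e-6

    def test_free_thresholds_agree_with_common_on_common_data(self, grm_fit_pair):
        R, _, free, _ = grm_fit_pair
        free_se = fit_grm(R, "common", "free", n_quadrature=21)
        free_t = fit_grm(R, "free", "free", n_quadrature=21, compute_se=False)
        assert np.max(np.abs(free_se.b - free_t.b) / free_se.se_b) < 2.0

    def test_reverse_coding_flips_locations(self):
        cfg = GeneratorConfig(
            n_persons=800, a=np.linspace(0.7, 2.0, 6), b=np.linspace(-1, 1.2, 6),
            t=np.array([-0.9, 0.0, 0.9]), seed=12,
        )
        R, _ = generate_grm(cfg)
        fit = fit_grm(R, "common", "free", n_quadrature=21, compute_se=False)
        Rrev = R.copy()
        Rrev.values = (R.n_categories - 1)[None, :] - R.values
        fit_rev = fit_grm(Rrev, "common", "free", n_quadrature=21, compute_se=False)
        np.testing.assert_allclose(fit_rev.a, fit.a, atol=0.05)
        np.testing.assert_allclose(fit_rev.b, -fit.b, atol=0.05)

    def test_recovery_improves_with_n(self):
        maes = {}
        for n in (200, 2000):
            errs = []
            for seed in range(10):
                cfg = GeneratorConfig(
                    n_persons=n, a=np.linspace(0.6, 2.2, 6),
                    b=np.linspace(-1, 1.2, 6), t=np.array([-0.9, 0.0, 0.9]),
                    seed=100 + seed,
                )
                R, truth = generate_grm(cfg)
                fit = fit_grm(R, "common", "free", n_quadrature=21, compute_se=False)
                errs.append(np.abs(fit.a - truth["a"]).mean())
            maes[n] = np.mean(errs)
        assert maes[2000] < maes[200]

    def test_empty_top_category_handled_free_thresholds(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 3, (120, 4))  # declared 5 categories, top 2 unused
        R = make_matrix(vals, n_categories=[5] * 4)
        fit = fit_grm(R, "free", "free", compute_se=False)
        assert fit.notes and np.all(fit.n_categories == 3)


class TestLRTest:
    def test_identical_fits_statistic_zero(self, grm_fit_pair):
        _, _, free, _ = grm_fit_pair
        constrained = GRMFit(**{**vars(free), "model_tag": "equal_a:common_t"})
        res = lr_test_equal_discrimination(constrained, free)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_df_is_items_minus_one(self, grm_fit_pair):
        _, _, free, equal = grm_fit_pair
        res = lr_test_equal_discrimination(equal, free)
        assert res.df == 5

    def test_detects_unequal_discriminations(self, grm_fit_pair):
        _, _, free, equal = grm_fit_pair
        res = lr_test_equal_discrimination(equal, free)
        assert res.statistic > 0 and res.p < 0.01


class TestScoring:
    def test_all_lowest_pattern_smallest_theta(self):
        fit = GRMFit.from_parameters(
            a=np.full(5, 1.4), b=np.linspace(-1, 1, 5), t=np.array([-0.8, 0.0, 0.8])
        )
        rng = np.random.default_rng(2)
        vals = np.vstack([np.zeros(5, dtype=int), rng.integers(0, 4, (30, 5))])
        R = make_matrix(vals, n_categories=[4] * 5)
        scores = score_persons(fit, R)
        assert scores.theta[0] == scores.theta.min()
        assert np.all(scores.theta[1:][(vals[1:] > 0).any(axis=1)] > scores.theta[0])

    def test_recenter_means_zero(self, grm_fit_pair):
        R, _, free, _ = grm_fit_pair
        raw = score_persons(free, R)
        shift = float(np.nanmean(raw.theta[raw.scored]))
        scores = score_persons(free, R, recenter=True)
        assert abs(np.nanmean(scores.theta[scores.scored])) < 1e-10
        np.testing.assert_allclose(scores.corrected_item_locations, free.b - shift)

    def test_doubling_instrument_shrinks_posterior_sd(self):
        a = np.linspace(0.8, 1.8, 5)
        b = np.linspace(-1, 1, 5)
        t = np.array([-0.8, 0.0, 0.8])
        cfg = GeneratorConfig(n_persons=40, a=a, b=b, t=t, seed=3)
        R, _ = generate_grm(cfg)
        single = GRMFit.from_parameters(a=a, b=b, t=t)
        double = GRMFit.from_parameters(a=np.tile(a, 2), b=np.tile(b, 2), t=t)
        R2 = make_matrix(np.hstack([R.values] * 2), n_categories=[4] * 10)
        s1 = score_persons(single, R)
        s2 = score_persons(double, R2)
        assert np.all(s2.se < s1.se)

    def test_all_missing_person_excluded(self):
        vals = np.array([[0, 1], [1, 1], [0, 0], [1, 0]])
        mask = np.array([[True, True], [False, False], [False, False], [False, False]])
        R = make_matrix(vals, n_categories=[2, 2], mask=mask)
        fit = GRMFit.from_parameters(a=np.array([1.0, 1.0]), b=np.array([0.0, 0.5]), t=np.array([0.0]))
        scores = score_persons(fit, R)
        assert scores.excluded == [0] and np.isnan(scores.theta[0])


class TestInformation:
    def test_dichotomous_reduces_to_2pl(self):
        fit = GRMFit.from_parameters(a=np.array([1.7]), b=np.array([0.5]), t=np.array([0.0]))
        info = item_information(fit, grid=(-3, 3, 0.01))
        from scipy.special import expit

        p = expit(1.7 * (info.theta - 0.5))
        np.testing.assert_allclose(info.item_info[0], 1.7**2 * p * (1 - p), atol=1e-10)
        assert info.item_info[0].max() == pytest.approx(1.7**2 / 4, abs=1e-4)

    def test_information_nonnegative_total_is_sum(self, grm_fit_pair):
        _, _, free, _ = grm_fit_pair
        info = item_information(free)
        assert np.all(info.item_info >= 0)
        np.testing.assert_allclose(info.total_info, info.item_info.sum(axis=0))

    def test_finite_difference_oracle(self):
        """I_i(theta) equals sum_k (dP_k/dtheta)^2 / P_k, i.e. the negative
        expected second derivative of the log-likelihood, by central differences."""
        fit = GRMFit.from_parameters(
            a=np.array([1.3, 2.1]), b=np.array([-0.4, 0.7]),
            t=np.array([-0.9, 0.1, 0.8]),
        )
        info = item_information(fit, grid=(-2, 2, 1.0))  # 5 grid points
        h = 1e-5
        for gi, th in enumerate(info.theta):
            Pp = grm_category_probs(fit, np.array([th + h]))[:, 0, :]
            Pm = grm_category_probs(fit, np.array([th - h]))[:, 0, :]
            P0 = grm_category_probs(fit, np.array([th]))[:, 0, :]
            dP = (Pp - Pm) / (2 * h)
            i_fd = (dP**2 / P0).sum(axis=1)
            np.testing.assert_allclose(info.item_info[:, gi], i_fd, atol=1e-4)

    def test_identical_items_equal_shares(self):
        fit = GRMFit.from_parameters(
            a=np.full(4, 1.0), b=np.zeros(4), t=np.array([-0.5, 0.5])
        )
        info = relative_information(item_information(fit))
        np.testing.assert_allclose(info.relative_share, 25.0, atol=1e-10)
        assert info.display_bucket == ["25"] * 4

    def test_vanishing_item_bucketed_below_five(self):
        fit = GRMFit.from_parameters(
            a=np.array([0.05, 1.5, 1.5, 1.5]), b=np.zeros(4), t=np.array([-0.5, 0.5])
        )
        info = relative_information(item_information(fit))
        assert info.display_bucket[0] == "<5"
        assert info.relative_share[0] < 5
        assert info.relative_share.sum() == pytest.approx(100.0)
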