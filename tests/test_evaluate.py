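import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scalestep import (
    GRMFit,
    GeneratorConfig,
    PipelineConfig,
    cronbach_alpha,
    evaluate_battery,
    flag_profiles,
    generate_grm,
    generate_multidim,
    generate_study_like,
    rank_concordance,
    rank_interval,
    run_three_step,
    score_persons,
)
from scalestep.evaluate import cronbach_alpha_values
from scalestep.exceptions import DegenerateItemError
from scalestep.irt import PersonScores
from conftest import guttman_matrix, make_matrix


def _scores(theta, se=None):
    theta = np.asarray(theta, dtype=float)
    se = np.full_like(theta, 0.3) if se is None else np.asarray(se, dtype=float)
    return PersonScores(
        theta=theta, se=se, scored=np.ones(theta.size, dtype=bool), recentered=False
    )


class TestCronbachAlpha:
    def test_two_perfectly_correlated_items(self):
        x = np.arange(10) % 4
        R = make_matrix(np.column_stack([x, x]), n_categories=[4, 4])
        assert cronbach_alpha(R) == pytest.approx(1.0)

    def test_known_covariance_structure(self):
        """Exact sample covariance diag(1,1,1) with off-diagonals 0.5 -> alpha 0.75."""
        rng = np.random.default_rng(0)
        n = 40
        Z = rng.standard_normal((n, 3))
        Z -= Z.mean(axis=0)
        # orthonormalise, then rescale to unit sample covariance
        Q, _ = np.linalg.qr(Z)
        Z = Q * np.sqrt(n - 1)
        S = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
        X = Z @ np.linalg.cholesky(S).T
        np.testing.assert_allclose(np.cov(X, rowvar=False), S, atol=1e-12)
        assert cronbach_alpha_values(X) == pytest.approx(0.75, abs=1e-12)

    def test_duplicating_items_increases_alpha(self):
        cfg = GeneratorConfig(
            n_persons=150, a=np.full(5, 1.2), b=np.linspace(-1, 1, 5),
            t=np.array([-0.8, 0.0, 0.8]), seed=2,
        )
        R, _ = generate_grm(cfg)
        doubled = make_matrix(np.hstack([R.values] * 2), n_categories=[4] * 10)
        assert cronbach_alpha(doubled) > cronbach_alpha(R)

    def test_zero_total_variance_degenerate(self):
        R = make_matrix(np.tile([0, 1], (6, 1)), n_categories=[2, 2])
        with pytest.raises(DegenerateItemError):
            cronbach_alpha(R)


class TestRankInterval:
    def test_zero_se_collapses_to_own_rank(self):
        s = _scores([0.1, 0.5, -0.3, 1.2], se=[1e-15, 0.3, 0.3, 0.3])
        ri = rank_interval(s, 0)
        assert ri.rank_lo == ri.rank == ri.rank_hi == 2

    def test_isolated_ci_keeps_own_rank(self):
        s = _scores([0.0, 5.0, -5.0], se=[0.1, 0.1, 0.1])
        ri = rank_interval(s, 0)
        assert ri.rank_lo == ri.rank_hi == ri.rank == 2

    def test_counting_oracle_random_configs(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = int(rng.integers(5, 60))
            theta = rng.standard_normal(n)
            se = rng.uniform(0.05, 0.8, n)
            s = _scores(theta, se)
            p = int(rng.integers(0, n))
            ri = rank_interval(s, p)
            z = 1.959963984540054
            lo_val, hi_val = theta[p] - z * se[p], theta[p] + z * se[p]
            others = np.delete(theta, p)
            assert ri.rank_lo == 1 + int((others < lo_val).sum())
            assert ri.rank_hi == 1 + int((others < hi_val).sum())
            assert 1 <= ri.rank_lo <= ri.rank <= ri.rank_hi <= n

    def test_relative_ranks_rounded_percent(self):
        s = _scores(np.linspace(-1, 1, 57), se=np.full(57, 0.2))
        ri = rank_interval(s, 19)  # rank 20 of 57
        assert ri.relative_rank == round(100 * 20 / 57) == 35


class TestRankConcordance:
    def test_identical_scores(self):
        s = _scores(np.linspace(-1, 1, 20))
        rho, frac = rank_concordance(s, s)
        assert rho == pytest.approx(1.0) and frac == 0.0

    def test_reversed_ranks_enumeration(self):
        n, thr = 40, 15
        theta = np.linspace(-1, 1, n)
        rho, frac = rank_concordance(_scores(theta), _scores(-theta), threshold=thr)
        expected = np.mean([abs((n + 1 - r) - r) >= thr for r in range(1, n + 1)])
        assert rho == pytest.approx(-1.0)
        assert frac == pytest.approx(expected)

    def test_shared_trait_instruments_concordant(self):
        from scalestep import fit_grm

        rhos = []
        for seed in range(10):
            R, truth = generate_study_like(seed)
            pair = []
            for name in ("AS-18-D", "PHQ9"):
                sl = truth["blocks"][name]
                blk = R.select_items(range(sl.start, sl.stop))
                fit = fit_grm(blk, "common", "free", n_quadrature=21, compute_se=False)
                pair.append(score_persons(fit, blk))
            rho, _ = rank_concordance(pair[0], pair[1])
            rhos.append(rho)
        assert np.median(rhos) > 0.7


class TestFlagProfiles:
    def test_constant_responder_flagged(self):
        cfg = GeneratorConfig(
            n_persons=60, a=np.full(6, 1.5), b=np.linspace(-1, 1, 6),
            t=np.array([-0.8, 0.0, 0.8]), seed=1,
        )
        R, _ = generate_grm(cfg)
        R.values[0] = 0
        fit = GRMFit.from_parameters(
            a=np.full(6, 1.5), b=np.linspace(-1, 1, 6), t=np.array([-0.8, 0.0, 0.8])
        )
        flags = flag_profiles(R, fit)
        assert any(f.person == 0 and f.reason == "constant" for f in flags)

    def test_random_responder_flagged_majority_of_seeds(self):
        a = np.full(9, 2.0)
        b = np.linspace(-1, 1.2, 9)
        t = np.array([-1.2, -0.4, 0.4, 1.2])
        fit = GRMFit.from_parameters(a=a, b=b, t=t)
        hits = 0
        for seed in range(20):
            cfg = GeneratorConfig(n_persons=300, a=a, b=b, t=t, n_random=1, seed=seed)
            R, _ = generate_grm(cfg)
            flags = flag_profiles(R, fit)
            hits += any(f.person == 300 and f.reason == "low_person_fit" for f in flags)
        assert hits > 10

    def test_coherent_median_person_not_flagged(self):
        a = np.full(9, 2.0)
        b = np.linspace(-1, 1.2, 9)
        t = np.array([-1.2, -0.4, 0.4, 1.2])
        fit = GRMFit.from_parameters(a=a, b=b, t=t)
        misses = 0
        for seed in range(20):
            cfg = GeneratorConfig(n_persons=50, a=a, b=b, t=t, latent_sd=1e-9, seed=seed)
            R, _ = generate_grm(cfg)  # everyone at theta ~= 0
            flags = flag_profiles(R, fit)
            misses += not any(f.person == 0 and f.reason == "low_person_fit" for f in flags)
        assert misses >= 15

    def test_interior_guttman_never_flagged(self):
        R = guttman_matrix(n_items=6, reps=8, interior_only=True)
        fit = GRMFit.from_parameters(
            a=np.full(6, 6.0), b=np.linspace(-1.5, 1.5, 6), t=np.array([0.0])
        )
        assert flag_profiles(R, fit) == []


class TestPipeline:
    def test_low_scalability_stops_after_step1(self):
        cfg = GeneratorConfig(
            n_persons=150, a=np.full(8, 0.4), b=np.linspace(-1, 1.5, 8),
            t=np.array([-0.8, 0.0, 0.8]), seed=2,
        )
        R, _ = generate_grm(cfg)
        report = run_three_step(R, PipelineConfig(bootstrap_B=50, seed=0))
        assert report.step1_gate.outcome == "stop"
        assert "0.3" in report.step1_gate.rule
        assert report.rsm is None and report.grm is None

    def test_mixed_discriminations_reject_step2_but_report_step3(self):
        cfg = GeneratorConfig(
            n_persons=300,
            a=np.array([0.6, 3.0, 0.6, 3.0, 0.6, 3.0, 0.6, 3.0]),
            b=np.linspace(-1, 1.2, 8), t=np.array([-0.8, 0.0, 0.8]), seed=4,
        )
        R, _ = generate_grm(cfg)
        report = run_three_step(R, PipelineConfig(bootstrap_B=50, seed=0))
        assert report.step1_gate.outcome == "proceed"
        assert report.step2_gate.outcome == "stop"
        assert report.grm is not None and report.scores is not None
        assert report.information.relative_share is not None
        assert report.coverage is not None

    def test_every_stage_present_or_skip_rule(self):
        cfg = GeneratorConfig(
            n_persons=200, a=np.full(6, 1.3), b=np.linspace(-0.8, 1, 6),
            t=np.array([-0.8, 0.0, 0.8]), seed=6,
        )
        R, _ = generate_grm(cfg)
        report = run_three_step(R, PipelineConfig(bootstrap_B=50, seed=1))
        assert report.step1_gate.outcome in ("proceed", "stop")
        if report.step1_gate.outcome == "proceed":
            assert report.rsm is not None or report.rsm_skip_rule
            assert report.step2_gate is not None and report.lr_test is not None
        # permutation tests recorded for every item below the lowerbound
        for item, h in zip(report.scalability.item_ids, report.scalability.h_item):
            if h < 0.3:
                assert item in report.permutation_tests

    def test_battery_cross_instrument_concordance(self):
        R, truth = generate_study_like(1)
        blocks = {
            name: R.select_items(range(sl.start, sl.stop))
            for name, sl in truth["blocks"].items()
            if name in ("AS-18-D", "PHQ9")
        }
        report = evaluate_battery(
            blocks, PipelineConfig(bootstrap_B=50, permutation_B=100, quadrature=21,
                                   compute_se=False, seed=0),
        )
        assert set(report.instruments) == set(blocks)
        done = [n for n, r in report.instruments.items() if r.scores is not None]
        if len(done) == 2:
            (pair, rho), = report.rank_correlations.items()
            assert rho > 0.5
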