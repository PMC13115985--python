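"""Latent class core: likelihood/E-step/M-step against enumeration oracles,
EM invariants (monotone trace, grid-search optimum, constraint preservation),
and the compiled-versus-reference inner-loop cross-check."""

import itertools

import numpy as np
import pytest

from cecdx.lca import (
    ConstraintSpec,
    EmptyClassError,
    LatentClassParams,
    _collapse,
    _em_run,
    _em_run_reference,
    _encode,
    e_step,
    fit_em,
    loglik,
    m_step,
    naive_accuracy,
)
from cecdx.records import TestPanel, build_test_panel
from cecdx.simulate import scenario_preset, simulate_cohort

from conftest import enum_mixture_loglik, enum_posterior, make_panel, random_panel

NAMES = ("laparoscopy", "CEC", "CA125")


def _params(pi, se, sp):
    return LatentClassParams(pi, np.asarray(se, float), np.asarray(sp, float), NAMES)


class TestLoglik:
    def test_uninformative_tests_give_log_half_per_result(self):
        """Se = 1-Sp = 0.5 for every test: each observed result contributes
        log(0.5) regardless of prevalence."""
        panel = make_panel([[1, 0, 1], [0, 0, 0], [1, 1, 1]])
        p = _params(0.3, [0.5] * 3, [0.5] * 3)
        assert loglik(panel, p) == pytest.approx(9 * np.log(0.5), abs=1e-12)

    def test_certain_data_under_perfect_tests_is_zero(self):
        panel = make_panel([[1, 1, 1], [0, 0, 0]])
        p = _params(0.5, [1.0] * 3, [1.0] * 3)
        # each row has probability pi or 1-pi
        assert loglik(panel, p) == pytest.approx(2 * np.log(0.5), abs=1e-12)

    def test_impossible_pattern_is_minus_inf(self):
        panel = make_panel([[1, 0, 0]])
        # Se_lap=0 and Sp_lap=1: a positive laparoscopy has probability zero
        p = _params(0.5, [0.0, 0.6, 0.6], [1.0, 0.8, 0.8])
        assert loglik(panel, p) == float("-inf")

    def test_matches_enumeration_oracle(self, rng):
        panel = random_panel(rng, 20)
        p = _params(0.37, [0.9, 0.6, 0.45], [0.95, 0.8, 0.7])
        want = enum_mixture_loglik(panel.results, 0.37,
                                   [0.9, 0.6, 0.45], [0.95, 0.8, 0.7])
        assert loglik(panel, p) == pytest.approx(want, rel=1e-12)

    def test_missing_entries_skipped_like_oracle(self, rng):
        panel = random_panel(rng, 30, missing=0.3)
        p = _params(0.5, [0.85, 0.6, 0.4], [0.9, 0.8, 0.75])
        want = enum_mixture_loglik(panel.results, 0.5,
                                   [0.85, 0.6, 0.4], [0.9, 0.8, 0.75])
        assert loglik(panel, p) == pytest.approx(want, rel=1e-12)

    def test_weights_scale_contributions(self, rng):
        panel = random_panel(rng, 10)
        p = _params(0.4, [0.8] * 3, [0.8] * 3)
        w = np.arange(1.0, 11.0)
        per_row = np.array([enum_mixture_loglik(panel.results[i:i + 1], 0.4,
                                                [0.8] * 3, [0.8] * 3)
                            for i in range(10)])
        assert loglik(panel, p, weights=w) == pytest.approx(
            float(w @ per_row), rel=1e-12)


class TestEStep:
    def test_uninformative_tests_return_prior(self):
        panel = make_panel([[1, 0, 1], [0, 0, 0]])
        p = _params(0.3, [0.5] * 3, [0.5] * 3)
        np.testing.assert_allclose(e_step(panel, p), 0.3, atol=1e-14)

    def test_perfect_specificity_positive_gives_one(self):
        """Sp_lap = 1: a positive laparoscopy cannot be a false positive."""
        panel = make_panel([[1, 0, 0], [0, 0, 0]])
        p = _params(0.2, [0.8, 0.6, 0.4], [1.0, 0.8, 0.75])
        g = e_step(panel, p)
        assert g[0] == pytest.approx(1.0, abs=1e-15)
        assert g[1] < 1.0

    def test_matches_bayes_oracle(self, rng):
        panel = random_panel(rng, 8, missing=0.25)
        pi, se, sp = 0.42, [0.88, 0.58, 0.37], [0.97, 0.81, 0.754]
        p = _params(pi, se, sp)
        g = e_step(panel, p)
        for i in range(8):
            assert g[i] == pytest.approx(
                enum_posterior(panel.results[i], pi, se, sp), rel=1e-12)


class TestMStep:
    def test_all_ones_gamma_raises_empty_class(self):
        panel = make_panel([[1, 0, 1], [0, 1, 0]])
        with pytest.raises(EmptyClassError):
            m_step(panel, np.ones(2), ConstraintSpec.none())

    def test_all_zeros_gamma_raises_empty_class(self):
        panel = make_panel([[1, 0, 1], [0, 1, 0]])
        with pytest.raises(EmptyClassError):
            m_step(panel, np.zeros(2), ConstraintSpec.none())

    def test_near_degenerate_gamma_approaches_observed_positivity(self):
        """gamma -> 1 everywhere: prevalence -> 1 and Se_k -> column mean."""
        panel = make_panel([[1, 0, 1], [1, 1, 0], [0, 0, 1], [1, 0, 1]])
        g = np.full(4, 1.0 - 1e-12)
        p = m_step(panel, g, ConstraintSpec.none())
        assert p.prevalence == pytest.approx(1.0, abs=1e-11)
        np.testing.assert_allclose(p.se, panel.results.mean(axis=0), atol=1e-9)

    def test_fixed_parameter_is_bitwise_exact(self, rng):
        panel = random_panel(rng, 25)
        g = rng.uniform(0.05, 0.95, 25)
        p = m_step(panel, g, ConstraintSpec.default("laparoscopy"))
        assert p.sp[0] == 1.0  # bit-exact, not approx

    def test_weighted_average_oracle(self, rng):
        panel = random_panel(rng, 12)
        g = rng.uniform(0.1, 0.9, 12)
        w = rng.uniform(0.5, 2.0, 12)
        p = m_step(panel, g, ConstraintSpec.none(), weights=w)
        y = panel.results
        wg, wh = w * g, w * (1 - g)
        assert p.prevalence == pytest.approx(wg.sum() / w.sum(), rel=1e-12)
        for k in range(3):
            assert p.se[k] == pytest.approx(
                (wg * y[:, k]).sum() / wg.sum(), rel=1e-12)
            assert p.sp[k] == pytest.approx(
                (wh * (1 - y[:, k])).sum() / wh.sum(), rel=1e-12)

    def test_missing_results_excluded(self):
        panel = make_panel([[1, np.nan, 1], [0, 1, 0], [1, 0, np.nan]])
        g = np.array([0.9, 0.2, 0.7])
        p = m_step(panel, g, ConstraintSpec.none())
        # CEC column: rows 1,2 observed
        wg = g[[1, 2]]
        y = np.array([1.0, 0.0])
        assert p.se[1] == pytest.approx((wg * y).sum() / wg.sum(), rel=1e-12)


class TestFitEm:
    def test_loglik_trace_is_monotone(self, rng):
        panel = random_panel(rng, 80, missing=0.1)
        fit = fit_em(panel, ConstraintSpec.default(), seed=0, n_restarts=3)
        diffs = np.diff(fit.loglik_trace)
        assert (diffs >= -1e-9).all()

    def test_em_attains_grid_optimum(self, rng):
        """EM log-likelihood >= best point on a 21^3 lattice over the free
        parameters (prevalence, Se_CEC, Se_CA125), all else fixed at truth."""
        cfg = scenario_preset("overall", n=40, seed=4)
        cohort, _ = simulate_cohort(cfg)
        panel = build_test_panel(cohort)
        fixed = {"sp:laparoscopy": 1.0, "se:laparoscopy": 0.88,
                 "sp:CEC": 0.81, "sp:CA125": 0.754}
        cons = ConstraintSpec(fixed=fixed)
        fit = fit_em(panel, cons, seed=1, n_restarts=10)
        # independent vectorized grid evaluation (not via package loglik)
        grid = np.linspace(0.0, 1.0, 21)
        y = panel.results
        best = -np.inf
        se = np.array([0.88, 0.0, 0.0])
        sp = np.array([1.0, 0.81, 0.754])
        for pi, s1, s2 in itertools.product(grid, grid, grid):
            se[1], se[2] = s1, s2
            a = np.prod(np.where(y == 1, se, 1 - se), axis=1)
            b = np.prod(np.where(y == 1, 1 - sp, sp), axis=1)
            mix = pi * a + (1 - pi) * b
            if (mix <= 0).any():
                continue
            ll = float(np.log(mix).sum())
            if ll > best:
                best = ll
        assert fit.loglik >= best - 1e-9

    def test_perfect_reference_recovers_naive_accuracy(self):
        """With a pseudo-test equal to true status fixed at (Se, Sp) = (1, 1),
        EM collapses to the closed-form cross-tabulation against the truth."""
        cfg = scenario_preset("overall", n=400, seed=6)
        cohort, truth = simulate_cohort(cfg)
        panel = build_test_panel(cohort)
        names = panel.test_names + ("oracle",)
        res = np.column_stack([panel.results, truth.true_status.astype(float)])
        aug = TestPanel(names, res, panel.patient_ids)
        cons = ConstraintSpec(fixed={"se:oracle": 1.0, "sp:oracle": 1.0},
                              anchor_test="oracle")
        fit = fit_em(aug, cons, seed=3, n_restarts=5)
        acc = naive_accuracy(aug, "oracle")
        for k, name in enumerate(("laparoscopy", "CEC", "CA125")):
            assert fit.params.se[k] == pytest.approx(acc[name][0], abs=1e-7)
            assert fit.params.sp[k] == pytest.approx(acc[name][1], abs=1e-7)
        assert fit.params.prevalence == pytest.approx(
            truth.true_status.mean(), abs=1e-7)

    def test_constraints_preserved_bitwise(self, rng):
        panel = random_panel(rng, 60)
        fit = fit_em(panel, ConstraintSpec.default("laparoscopy"),
                     seed=2, n_restarts=4)
        assert fit.params.sp[0] == 1.0

    def test_anchor_youden_nonnegative(self, rng):
        for s in range(4):
            panel = random_panel(np.random.default_rng(s), 50)
            fit = fit_em(panel, ConstraintSpec.none(), seed=s, n_restarts=6)
            assert fit.params.youden("laparoscopy") >= -1e-12

    def test_two_tests_unconstrained_flagged(self, rng):
        panel = random_panel(rng, 40, k=2)
        with pytest.warns(UserWarning, match="non_identifiable"):
            fit = fit_em(panel, ConstraintSpec.none(), seed=0, n_restarts=2)
        assert any("non_identifiable" in f for f in fit.flags)

    def test_deterministic_under_seed(self, rng):
        panel = random_panel(rng, 70, missing=0.1)
        a = fit_em(panel, seed=11, n_restarts=5)
        b = fit_em(panel, seed=11, n_restarts=5)
        assert a.loglik == b.loglik
        np.testing.assert_array_equal(a.params.se, b.params.se)

    def test_recovers_generating_truth_moderate_n(self):
        """Averaged over a few cohorts, the constrained EM recovers the
        generating operating characteristics."""
        ests = []
        for seed in range(20, 25):
            cfg = scenario_preset("overall", n=2000, seed=seed)
            cohort, _ = simulate_cohort(cfg)
            panel = build_test_panel(cohort)
            fit = fit_em(panel, seed=0, n_restarts=5)
            ests.append(fit.params.as_dict())
        mean = {k: np.mean([e[k] for e in ests]) for k in ests[0]}
        assert abs(mean["prevalence"] - 0.48) < 0.05
        assert abs(mean["se_CEC"] - 0.58) < 0.05
        assert abs(mean["sp_CEC"] - 0.81) < 0.05

    def test_weights_equal_replication(self, rng):
        """Integer weights act exactly like replicated rows."""
        panel = random_panel(rng, 15)
        w = rng.integers(1, 4, 15).astype(float)
        rep_rows = np.repeat(panel.results, w.astype(int), axis=0)
        rep_panel = TestPanel(panel.test_names, rep_rows,
                              tuple(f"r{i}" for i in range(rep_rows.shape[0])))
        fa = fit_em(panel, seed=5, n_restarts=3, weights=w)
        fb = fit_em(rep_panel, seed=5, n_restarts=3)
        assert fa.loglik == pytest.approx(fb.loglik, rel=1e-9)
        np.testing.assert_allclose(fa.params.se, fb.params.se, atol=1e-7)


class TestCompiledVsReference:
    def test_compiled_loop_matches_numpy_reference(self, rng):
        """The (possibly numba-compiled) inner loop and the retained numpy
        implementation agree from the same start on the same patterns."""
        for s in range(3):
            panel = random_panel(np.random.default_rng(100 + s), 200,
                                 missing=0.15)
            enc = _encode(panel.results)
            patterns, wts, _ = _collapse(enc, None)
            init = LatentClassParams(0.4, np.array([0.8, 0.7, 0.6]),
                                     np.array([0.9, 0.8, 0.7]), NAMES)
            cons = ConstraintSpec.default("laparoscopy")
            pa, lla, _, _ = _em_run(patterns, wts, NAMES, cons, init,
                                    1e-10, 3000)
            pb, llb, _, _ = _em_run_reference(patterns, wts, NAMES, cons,
                                              init, 1e-10, 3000)
            assert lla == pytest.approx(llb, abs=1e-9)
            np.testing.assert_allclose(pa.se, pb.se, atol=1e-10)
            np.testing.assert_allclose(pa.sp, pb.sp, atol=1e-10)
            assert pa.prevalence == pytest.approx(pb.prevalence, abs=1e-10)


class TestNaiveAccuracy:
    def test_identical_test_scores_perfectly(self):
        panel = make_panel([[1, 1, 0], [0, 0, 1], [1, 1, 1], [0, 0, 0]])
        acc = naive_accuracy(panel, "laparoscopy")
        assert acc["CEC"] == (1.0, 1.0)

    def test_complement_test_scores_zero(self):
        panel = make_panel([[1, 0, 0], [0, 1, 1], [1, 0, 1], [0, 1, 0]])
        acc = naive_accuracy(panel, "laparoscopy")
        assert acc["CEC"] == (0.0, 0.0)

    def test_printed_count_fixture(self):
        """86 reference-positive with 55 CEC-positive and 146 reference-negative
        with 36 CEC-positive: Se = 55/86, Sp = 110/146."""
        rows = ([[1, 1, 0]] * 55 + [[1, 0, 0]] * 31
                + [[0, 1, 0]] * 36 + [[0, 0, 0]] * 110)
        panel = make_panel(rows)
        acc = naive_accuracy(panel, "laparoscopy")
        assert acc["CEC"][0] == pytest.approx(55 / 86, rel=1e-12)
        assert acc["CEC"][1] == pytest.approx(110 / 146, rel=1e-12)

    def test_incomplete_reference_rejected(self):
        panel = make_panel([[np.nan, 1, 0], [0, 0, 1]])
        with pytest.raises(ValueError):
            naive_accuracy(panel, "laparoscopy")
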