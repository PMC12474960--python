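"""REML engine: closed-form oracles, boundary behavior, LRT, selection."""

import numpy as np
import pandas as pd
import pytest

from jucara import lmm, simulate
from jucara.lmm import ModelSpec, RandomSpec, ResidualSpec


def anova_one_way(table: pd.DataFrame):
    """Closed-form balanced one-way ANOVA estimators (independent oracle)."""
    wide = table.pivot_table(index="genotype", columns="replicate", values="value")
    y = wide.to_numpy()
    i, r = y.shape
    gmeans = y.mean(axis=1)
    grand = y.mean()
    msb = r * np.sum((gmeans - grand) ** 2) / (i - 1)
    msw = np.sum((y - gmeans[:, None]) ** 2) / (i * (r - 1))
    return (msb - msw) / r, msw, gmeans, grand, r


GSPEC = ModelSpec(response="trait", fixed=(), random=(RandomSpec("genotype"),))


class TestRemlOracle:
    def test_matches_anova_estimators(self, biometric_20x5):
        table, _ = biometric_20x5
        s2g, s2e, *_ = anova_one_way(table)
        fit = lmm.fit_reml(table, GSPEC)
        assert fit.sigma2_g == pytest.approx(s2g, rel=1e-6)
        assert fit.residual_var == pytest.approx(s2e, rel=1e-6)

    def test_blups_are_shrunken_genotype_means(self, biometric_20x5):
        table, _ = biometric_20x5
        s2g, s2e, gmeans, grand, r = anova_one_way(table)
        h = s2g / (s2g + s2e / r)
        expected = h * (gmeans - grand)
        got = lmm.fit_reml(table, GSPEC).genotype_blups.to_numpy()
        assert np.allclose(got, expected, atol=1e-6)

    def test_blups_sum_to_zero(self, biometric_20x5):
        table, _ = biometric_20x5
        fit = lmm.fit_reml(table, GSPEC)
        assert abs(fit.genotype_blups.sum()) < 1e-6

    def test_zero_genotype_spread_hits_boundary(self):
        rows = [
            ("G%02d" % g, rep, "trait", float(rep))  # identical genotype profiles
            for g in range(10)
            for rep in range(1, 5)
        ]
        table = pd.DataFrame(rows, columns=["genotype", "replicate", "trait", "value"])
        fit = lmm.fit_reml(table, GSPEC)
        assert fit.sigma2_g < 1e-6

    def test_row_order_invariance(self, biometric_20x5):
        table, _ = biometric_20x5
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        f1 = lmm.fit_reml(table, GSPEC)
        f2 = lmm.fit_reml(shuffled, GSPEC)
        # identical optimum up to optimizer path noise
        assert f1.sigma2_g == pytest.approx(f2.sigma2_g, rel=1e-5)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)

    def test_monotone_loglik_trace(self, biometric_20x5):
        table, _ = biometric_20x5
        fit = lmm.fit_reml(table, GSPEC)
        assert fit.converged
        trace = np.asarray(fit.ll_trace)
        assert (np.diff(trace) >= 0).all()

    def test_rank_deficient_fixed_design_errors(self, biometric_20x5):
        table, _ = biometric_20x5
        table = table.copy()
        table["dup"] = table["replicate"]  # perfectly aliased factor
        spec = ModelSpec(
            response="trait", fixed=("replicate", "dup"), random=(RandomSpec("genotype"),)
        )
        with pytest.raises(ValueError, match="aliased"):
            lmm.fit_reml(table, spec)

    def test_unbalanced_data_fit(self, biometric_20x5):
        table, _ = biometric_20x5
        thinned = table.sample(frac=0.8, random_state=1)
        fit = lmm.fit_reml(thinned, GSPEC)
        assert fit.converged and fit.sigma2_g > 0


class TestGeneticParameters:
    def test_cullis_h2_matches_balanced_closed_form(self):
        cfg = simulate.SimulationConfig(
            n_genotypes=50, n_reps=5, sigma2_g=2.0, sigma2_e=1.0, seed=13
        )
        table, _ = simulate.simulate_biometric(cfg)
        fit = lmm.fit_reml(table, GSPEC)
        closed = fit.sigma2_g / (fit.sigma2_g + fit.residual_var / 5)
        assert lmm.cullis_heritability(fit) == pytest.approx(closed, abs=0.02)

    def test_accuracy_consistent_with_h2(self):
        # balanced case: mean r ≈ sqrt(H²); the PEV diagonal carries an extra
        # O(1/n_genotypes) intercept-uncertainty term, hence the tolerance
        cfg = simulate.SimulationConfig(
            n_genotypes=50, n_reps=5, sigma2_g=2.0, sigma2_e=1.0, seed=13
        )
        table, _ = simulate.simulate_biometric(cfg)
        fit = lmm.fit_reml(table, GSPEC)
        _, mean_acc = lmm.prediction_accuracy(fit)
        assert mean_acc == pytest.approx(np.sqrt(lmm.cullis_heritability(fit)), abs=0.02)

    def test_zero_pev_limits(self, biometric_20x5):
        table, _ = biometric_20x5
        fit = lmm.fit_reml(table, GSPEC)
        fit.pev[fit._genotype_name()] = np.zeros_like(fit.pev_matrix)
        assert lmm.cullis_heritability(fit) == pytest.approx(1.0)
        _, acc = lmm.prediction_accuracy(fit)
        assert acc == pytest.approx(1.0)

    def test_us_interaction_recovery(self):
        # the identified quantity is the total per-time genotypic variance
        # sigma2_g + diag(G_gm) absorbed into the unstructured matrix
        Ggm = np.array([[1.0, 0.3, 0.1], [0.3, 2.0, 0.5], [0.1, 0.5, 3.0]])
        spec = ModelSpec(
            response="trait",
            fixed=("replicate", "eval_time"),
            random=(RandomSpec("genotype", structure="us", by="eval_time"),),
            residual=ResidualSpec(by="eval_time"),
        )
        diags = []
        for s in range(50):
            cfg = simulate.SimulationConfig(
                n_genotypes=40, n_reps=4, n_times=3, sigma2_g=1.0, sigma2_e=1.0,
                G_gm=Ggm, seed=300 + s,
            )
            table, _ = simulate.simulate_growth(cfg)
            fit = lmm.fit_reml(table, spec, polish=False)
            diags.append(np.diag(fit.varcomps["genotype:eval_time"]))
        mean_diag = np.mean(diags, axis=0)
        truth = 1.0 + np.diag(Ggm)
        assert np.all(np.abs(mean_diag - truth) / truth < 0.25)


class TestLRT:
    FULL = ModelSpec(response="trait", fixed=("replicate",), random=(RandomSpec("genotype"),))
    REDUCED = ModelSpec(response="trait", fixed=("replicate",), random=())

    def test_identical_models_give_zero(self, biometric_20x5):
        table, _ = biometric_20x5
        fit = lmm.fit_reml(table, self.FULL)
        res = lmm.lrt(fit, fit)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_type_i_error_conservative_under_null(self):
        rej = 0
        n_sims = 200
        for s in range(n_sims):
            cfg = simulate.SimulationConfig(
                n_genotypes=20, n_reps=4, sigma2_g=0.0, sigma2_e=1.0, seed=1000 + s
            )
            table, _ = simulate.simulate_biometric(cfg)
            full = lmm.fit_reml(table, self.FULL, polish=False)
            red = lmm.fit_reml(table, self.REDUCED, polish=False)
            if lmm.lrt(full, red).p_value < 0.05:
                rej += 1
        assert rej / n_sims <= 0.05

    def test_power_against_large_genetic_variance(self):
        hits = 0
        for s in range(50):
            cfg = simulate.SimulationConfig(
                n_genotypes=30, n_reps=5, sigma2_g=4.0, sigma2_e=1.0, seed=2000 + s
            )
            table, _ = simulate.simulate_biometric(cfg)
            full = lmm.fit_reml(table, self.FULL, polish=False)
            red = lmm.fit_reml(table, self.REDUCED, polish=False)
            if lmm.lrt(full, red).p_value < 0.001:
                hits += 1
        assert hits >= 48  # >= 95%

    def test_elevation_term_type_i(self):
        # no elevation variance simulated → its LRT should rarely reject
        full = ModelSpec(
            response="trait",
            fixed=("replicate", "group"),
            random=(RandomSpec("genotype"), RandomSpec("elevation")),
            residual=ResidualSpec(by="group"),
        )
        reduced = ModelSpec(
            response="trait",
            fixed=("replicate", "group"),
            random=(RandomSpec("genotype"),),
            residual=ResidualSpec(by="group"),
        )
        nonsig = 0
        n_sims = 100
        for s in range(n_sims):
            cfg = simulate.SimulationConfig(
                n_genotypes=24, n_emergence_reps=4, sigma2_g=1.0, sigma2_al=0.0,
                sigma2_e=1.0, n_elevations=3, n_groups=2, seed=3000 + s,
            )
            table, _, _ = simulate.simulate_emergence(cfg)
            f = lmm.fit_reml(table, full, polish=False)
            r = lmm.fit_reml(table, reduced, polish=False)
            if lmm.lrt(f, r).p_value >= 0.05:
                nonsig += 1
        assert nonsig >= 0.90 * n_sims

    def test_non_nested_rejected(self, biometric_20x5):
        table, _ = biometric_20x5
        full = lmm.fit_reml(table, self.FULL)
        red = lmm.fit_reml(table, self.REDUCED)
        with pytest.raises(ValueError, match="not nested"):
            lmm.lrt(red, full)


class TestInformationCriteria:
    def test_aic_difference_for_one_extra_param(self):
        a1 = lmm.information_criteria(loglik=-100.0, n_params=3, n_obs=50, rank_x=2)[0]
        a2 = lmm.information_criteria(loglik=-100.0, n_params=4, n_obs=50, rank_x=2)[0]
        assert a2 - a1 == pytest.approx(2.0)

    def test_zero_params_all_equal_minus_2ll(self):
        aic, bic, bicc = lmm.information_criteria(
            loglik=-123.4, n_params=0, n_obs=80, rank_x=3
        )
        assert aic == bic == bicc == pytest.approx(246.8)

    def test_hand_computed_values(self):
        # l = -50, p = 2, n = 100, rank X = 4
        aic, bic, bicc = lmm.information_criteria(
            loglik=-50.0, n_params=2, n_obs=100, rank_x=4
        )
        assert aic == pytest.approx(104.0)
        assert bic == pytest.approx(100.0 + 2 * np.log(100))
        assert bicc == pytest.approx(100.0 + 2 * np.log(96))  # REML effective n


class TestStructureSelection:
    def test_single_candidate_returned(self, biometric_20x5):
        table, _ = biometric_20x5
        tab, best, fits = lmm.select_structure(table, [GSPEC])
        assert best == GSPEC and len(tab) == 1

    def test_diag_residual_detected(self):
        homo = ModelSpec(
            response="trait", fixed=("replicate", "eval_time"),
            random=(RandomSpec("genotype"),),
        )
        diag = ModelSpec(
            response="trait", fixed=("replicate", "eval_time"),
            random=(RandomSpec("genotype"),), residual=ResidualSpec(by="eval_time"),
        )
        wins = 0
        for s in range(50):
            cfg = simulate.SimulationConfig(
                n_genotypes=30, n_reps=3, n_times=3, sigma2_g=1.0,
                time_resid_var=np.array([0.3, 1.0, 3.0]), seed=4000 + s,
            )
            table, _ = simulate.simulate_growth(cfg)
            _, best, _ = lmm.select_structure(table, [homo, diag])
            if best is diag:
                wins += 1
        assert wins >= 40  # >= 80% of 50

    def test_failing_candidate_flagged_and_excluded(self, biometric_20x5):
        table, _ = biometric_20x5
        table = table.copy()
        table["dup"] = table["replicate"]
        bad = ModelSpec(
            response="trait", fixed=("replicate", "dup"), random=(RandomSpec("genotype"),)
        )
        with pytest.warns(UserWarning, match="failed"):
            tab, best, _ = lmm.select_structure(table, [bad, GSPEC])
        assert best == GSPEC
        assert not tab.set_index("model").loc[bad.describe(), "converged"]
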