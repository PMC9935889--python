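"""Mixed-model meta-analysis: REML oracles, bootstrap CIs, hypothesis readout."""

import numpy as np
import pandas as pd
import pytest

import magbias as mb
from magbias.meta import _build_design, _fit_mixed


def profiled_reml(y, X, codes, ratio):
    """Hand-written profiled REML criterion at variance ratio s2b/s2e.

    Profiles out the residual variance analytically; used as an
    independent oracle for the REML optimum.
    """
    n, p = X.shape
    n_groups = codes.max() + 1
    Z = np.zeros((n, n_groups))
    Z[np.arange(n), codes] = 1.0
    W = np.eye(n) + ratio * Z @ Z.T
    Wi = np.linalg.inv(W)
    XtWiX = X.T @ Wi @ X
    beta = np.linalg.solve(XtWiX, X.T @ Wi @ y)
    r = y - X @ beta
    quad = r @ Wi @ r
    s2e = quad / (n - p)
    _, ldW = np.linalg.slogdet(W)
    _, ldX = np.linalg.slogdet(XtWiX)
    return -0.5 * (ldW + (n - p) * np.log(s2e) + ldX + (n - p))


def simulate_slope_table(n_modules=60, sigma_module=0.5, sigma_resid=0.2,
                         steps_coef=-0.05, phylum_effects=(0.0, 0.2, 0.4, 0.6),
                         seed=0):
    rng = np.random.default_rng(seed)
    phyla = list(mb.DEFAULT_PHYLA)
    domains = ["Amino acid metabolism", "Energy metabolism", "Lipid metabolism"]
    rows = []
    for m in range(n_modules):
        steps = int(rng.integers(2, 20))
        domain = domains[m % len(domains)]
        b = rng.normal(0.0, sigma_module)
        for p, eff in zip(phyla, phylum_effects):
            slope = 3.0 + eff + steps_coef * steps + b + rng.normal(0.0, sigma_resid)
            rows.append({"module_id": f"M{m:03d}", "phylum": p, "slope": slope,
                         "se": 0.1, "domain": domain, "n_steps": steps})
    return pd.DataFrame(rows)


class TestFitSlopeLmm:
    def test_constant_slopes_collapse_to_zero_variance(self):
        table = simulate_slope_table(sigma_module=0.0, sigma_resid=0.0,
                                     steps_coef=0.0, phylum_effects=(0, 0, 0, 0), seed=1)
        fit = mb.fit_slope_lmm(table)
        assert fit.singular
        assert fit.sigma2_module + fit.sigma2_resid < 1e-8
        non_intercept = fit.fe_params.drop("Intercept")
        np.testing.assert_allclose(non_intercept.to_numpy(), 0.0, atol=1e-6)

    def test_shift_moves_only_the_intercept(self):
        table = simulate_slope_table(seed=2)
        shifted = table.assign(slope=table["slope"] + 5.0)
        a, b = mb.fit_slope_lmm(table), mb.fit_slope_lmm(shifted)
        assert b.fe_params["Intercept"] - a.fe_params["Intercept"] == pytest.approx(5.0, abs=1e-6)
        pd.testing.assert_series_equal(
            a.fe_params.drop("Intercept"), b.fe_params.drop("Intercept"), atol=1e-6
        )

    def test_reml_matches_grid_search_oracle(self):
        table = simulate_slope_table(n_modules=40, seed=3)
        fit = mb.fit_slope_lmm(table)
        X, _ = _build_design(table, fit.ref_phylum, fit.ref_domain,
                             fit.phylum_levels, fit.domain_levels)
        y = table["slope"].to_numpy()
        codes = pd.factorize(table["module_id"])[0]
        fitted_ratio = fit.sigma2_module / fit.sigma2_resid
        ll_fit = profiled_reml(y, X, codes, fitted_ratio)
        grid = np.linspace(0.0, max(4 * fitted_ratio, 2.0), 400)
        ll_grid = max(profiled_reml(y, X, codes, r) for r in grid)
        assert ll_fit >= ll_grid - 1e-4

    def test_balanced_oneway_matches_anova_closed_form(self):
        # intercept-only model on balanced groups: REML = ANOVA estimators
        rng = np.random.default_rng(4)
        n_groups, k = 30, 5
        b = rng.normal(0, 0.7, n_groups)
        y = (2.0 + np.repeat(b, k) + rng.normal(0, 0.3, n_groups * k))
        groups = np.repeat([f"m{i}" for i in range(n_groups)], k)
        X = np.ones((len(y), 1))
        _, _, s2b, s2e, _ = _fit_mixed(y, X, groups, ["Intercept"])
        ym = y.reshape(n_groups, k)
        msw = ((ym - ym.mean(axis=1, keepdims=True)) ** 2).sum() / (n_groups * (k - 1))
        msb = k * ((ym.mean(axis=1) - ym.mean()) ** 2).sum() / (n_groups - 1)
        assert s2e == pytest.approx(msw, rel=1e-3)
        assert s2b == pytest.approx((msb - msw) / k, rel=1e-3, abs=1e-3)

    def test_steps_coefficient_recovered(self):
        hits = 0
        for rep in range(10):
            table = simulate_slope_table(n_modules=200, steps_coef=-0.05, seed=100 + rep)
            fit = mb.fit_slope_lmm(table)
            est = fit.fe_params["n_steps"]
            se = fit.fe_se["n_steps"]
            if abs(est - (-0.05)) < 1.96 * se:
                hits += 1
        assert hits >= 8

    def test_too_few_modules_rejected(self):
        table = simulate_slope_table(n_modules=1)
        with pytest.raises(ValueError):
            mb.fit_slope_lmm(table)


class TestMarginalPredictions:
    def test_equal_levels_when_no_effects(self):
        table = simulate_slope_table(phylum_effects=(0, 0, 0, 0), steps_coef=0.0,
                                     sigma_module=0.3, sigma_resid=0.1, seed=5)
        fit = mb.fit_slope_lmm(table)
        preds = mb.marginal_predictions(fit, "phylum")
        assert preds.max() - preds.min() < 0.2

    def test_constructed_ordering_is_recovered(self):
        # Proteobacteria gets the largest generative effect
        table = simulate_slope_table(phylum_effects=(0.0, -0.1, 0.1, 0.5),
                                     sigma_resid=0.05, sigma_module=0.2, seed=6)
        fit = mb.fit_slope_lmm(table)
        preds = mb.marginal_predictions(fit, "phylum")
        assert preds.idxmax() == "Proteobacteria"

    def test_invariant_to_row_order(self):
        table = simulate_slope_table(seed=7)
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = mb.marginal_predictions(mb.fit_slope_lmm(table), "phylum")
        b = mb.marginal_predictions(mb.fit_slope_lmm(shuffled), "phylum")
        pd.testing.assert_series_equal(a, b, atol=1e-6)

    def test_unknown_focal_rejected(self):
        fit = mb.fit_slope_lmm(simulate_slope_table(seed=8))
        with pytest.raises(ValueError):
            mb.marginal_predictions(fit, "steps")


@pytest.fixture(scope="module")
def small_fit():
    table = simulate_slope_table(n_modules=25, seed=9)
    return mb.fit_slope_lmm(table), table


class TestBootstrap:
    def test_reproducible_bit_for_bit(self, small_fit):
        fit, table = small_fit
        a = mb.bootstrap_cis(fit, table, n_sim=30, seed=11)
        b = mb.bootstrap_cis(fit, table, n_sim=30, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_records_requested_simulations(self, small_fit):
        fit, table = small_fit
        cis = mb.bootstrap_cis(fit, table, n_sim=30, seed=12)
        assert (cis["n_boot"] == 30).all()
        assert set(cis["factor"]) == {"phylum", "domain", "steps"}
        assert (cis["lo"] <= cis["estimate"]).all()
        assert (cis["estimate"] <= cis["hi"]).all()

    def test_ci_width_shrinks_with_vanishing_noise(self):
        wide = simulate_slope_table(sigma_module=0.5, sigma_resid=0.3, seed=13)
        tight = simulate_slope_table(sigma_module=0.01, sigma_resid=0.01, seed=13)
        w = mb.bootstrap_cis(mb.fit_slope_lmm(wide), wide, n_sim=30, seed=14)
        t = mb.bootstrap_cis(mb.fit_slope_lmm(tight), tight, n_sim=30, seed=14)
        ww = (w["hi"] - w["lo"]).mean()
        tw = (t["hi"] - t["lo"]).mean()
        assert tw < ww / 5


class TestEvaluateHypotheses:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["factor", "level", "estimate", "lo", "hi",
                                           "n_boot"])

    def test_disjoint_cis_flag_a_difference(self):
        cis = self._table([
            ("phylum", "A", 1.5, 1.0, 2.0, 99),
            ("phylum", "B", 3.5, 3.0, 4.0, 99),
            ("steps", "n_steps", -0.04, -0.08, -0.01, 99),
        ])
        findings = mb.evaluate_hypotheses(cis)
        assert findings["phylum"] == [("A", "B")]
        assert findings["steps"]["direction"] == "negative"
        text = mb.format_findings(findings)
        assert "do not overlap" in text and "negative" in text

    def test_overlapping_cis_give_no_evidence(self):
        cis = self._table([
            ("phylum", "A", 2.0, 1.0, 3.0, 99),
            ("phylum", "B", 3.0, 2.0, 4.0, 99),
            ("steps", "n_steps", 0.01, -0.02, 0.04, 99),
        ])
        findings = mb.evaluate_hypotheses(cis)
        assert findings["phylum"] == []
        assert findings["steps"]["direction"] is None
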