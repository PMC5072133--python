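"""Factorial design matrix, profiled-REML fitter, treatment means, quadrants."""

import numpy as np
import pandas as pd
import pytest

import perivar as pv
from perivar.errors import DesignMatrixError, ValidationError
from perivar.lmm import LmmFit
from _oracles import grid_search_reml

TABLE_DIATOM_BETA = np.array(
    [1.251, -0.156, -0.155, -0.230, -0.158, 0.207, 0.102, 0.109, 0.217]
)


def balanced_layout(n_taxa=8):
    taxa = np.repeat([f"g{k}" for k in range(n_taxa)], 9)
    treatments = np.tile(pv.TREATMENTS, n_taxa)
    return taxa, treatments, pv.build_design_matrix(treatments)


def simulate_y(X, taxa, beta, sd_taxon, sd_resid, seed):
    rng = np.random.default_rng(seed)
    labels, codes = np.unique(taxa, return_inverse=True)
    return (
        X.to_numpy() @ beta
        + rng.normal(0, sd_taxon, labels.size)[codes]
        + rng.normal(0, sd_resid, len(taxa))
    )


class TestDesignMatrix:
    def test_reference_cell(self):
        row = pv.build_design_matrix(["AA"]).iloc[0]
        assert row["Intercept"] == 1 and row.drop("Intercept").sum() == 0

    def test_double_depth_cell(self):
        row = pv.build_design_matrix(["DD"]).iloc[0]
        on = {c for c in row.index if row[c] == 1}
        assert on == {"Intercept", "T1D", "T2D", "T1D:T2D"}

    def test_full_rank_over_nine_treatments(self):
        X = pv.build_design_matrix(pv.TREATMENTS)
        assert np.linalg.matrix_rank(X.to_numpy()) == 9

    def test_within_time_products_are_zero(self):
        X = pv.build_design_matrix(pv.TREATMENTS)
        assert (X["T1D"] * X["T1S"]).sum() == 0
        assert (X["T2D"] * X["T2S"]).sum() == 0

    def test_invalid_code(self):
        with pytest.raises(DesignMatrixError):
            pv.build_design_matrix(["AA", "XX"])


class TestFitReml:
    def test_noiseless_limit_recovers_beta_exactly(self):
        taxa, _, X = balanced_layout(4)
        beta = np.arange(9, dtype=float) / 10 + 0.5
        y = X.to_numpy() @ beta
        fit = pv.fit_reml(y, X, taxa)
        assert np.abs(fit.beta - beta).max() < 1e-8
        assert fit.sigma2_resid < 1e-10 and fit.sigma2_taxon < 1e-10

    def test_balanced_reml_equals_ols_and_aa_mean(self):
        taxa, treatments, X = balanced_layout(8)
        y = simulate_y(X, taxa, TABLE_DIATOM_BETA, 0.155, 0.13, seed=2)
        fit = pv.fit_reml(y, X, taxa)
        ols = np.linalg.lstsq(X.to_numpy(), y, rcond=None)[0]
        assert np.abs(fit.beta - ols).max() < 1e-8
        assert fit.beta[0] == pytest.approx(y[treatments == "AA"].mean(), abs=1e-8)

    def test_saturated_means_equal_cell_means(self):
        taxa, treatments, X = balanced_layout(6)
        y = simulate_y(X, taxa, TABLE_DIATOM_BETA, 0.1, 0.2, seed=3)
        fit = pv.fit_reml(y, X, taxa)
        means = pv.treatment_means(fit)
        for t in pv.TREATMENTS:
            assert means[t] == pytest.approx(y[treatments == t].mean(), abs=1e-8)

    def test_blups_sum_to_zero_in_balanced_design(self):
        taxa, _, X = balanced_layout(8)
        y = simulate_y(X, taxa, TABLE_DIATOM_BETA, 0.2, 0.1, seed=4)
        fit = pv.fit_reml(y, X, taxa)
        assert abs(fit.taxon_effects.sum()) < 1e-8

    def test_matches_grid_search_on_unbalanced_data(self):
        rng = np.random.default_rng(7)
        taxa = np.repeat([f"g{k}" for k in range(9)], 9)
        treatments = np.tile(pv.TREATMENTS, 9)
        keep = np.sort(rng.choice(81, size=72, replace=False))
        taxa, treatments = taxa[keep], treatments[keep]
        X = pv.build_design_matrix(treatments)
        y = simulate_y(X, taxa, TABLE_DIATOM_BETA, 0.2, 0.12, seed=8)
        fit = pv.fit_reml(y, X, taxa)
        codes = pd.factorize(taxa)[0]
        oracle = grid_search_reml(y, X.to_numpy(), codes, n_grid=800)
        # beta varies with lambda on unbalanced data, so its agreement is
        # bounded by the oracle's grid resolution
        assert np.abs(fit.beta - oracle["beta"]).max() < 1e-4
        res = 20.0 / 800
        assert abs(np.log(max(fit.lambda_, 1e-12)) - np.log(max(oracle["lam"], 1e-12))) < 2 * res

    def test_agrees_with_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(12)
        taxa = np.repeat([f"g{k}" for k in range(10)], 9)
        treatments = np.tile(pv.TREATMENTS, 10)
        keep = rng.random(90) < 0.9
        taxa, treatments = taxa[keep], treatments[keep]
        X = pv.build_design_matrix(treatments)
        y = simulate_y(X, taxa, TABLE_DIATOM_BETA, 0.18, 0.11, seed=13)
        fit = pv.fit_reml(y, X, taxa)
        mf = sm.MixedLM(y, X.to_numpy(), groups=taxa).fit(reml=True)
        assert np.abs(fit.beta - mf.fe_params).max() < 1e-4
        assert fit.sigma2_taxon == pytest.approx(float(np.asarray(mf.cov_re)[0, 0]), abs=1e-4)
        assert fit.sigma2_resid == pytest.approx(float(mf.scale), abs=1e-4)
        assert np.abs(fit.se - mf.bse_fe).max() < 1e-4

    def test_diatom_shaped_output_structure(self, diatom_dataset):
        comm, design = diatom_dataset["community"], diatom_dataset["design"]
        rec = pv.variability_table(comm, design, pv.select_common_taxa(comm, 8))
        X = pv.build_design_matrix(rec["treatment"])
        fit = pv.fit_reml(rec["sqrt_cv"].to_numpy(), X, rec["taxon_id"].to_numpy())
        tab = fit.coef_table()
        assert list(tab["term"]) == list(pv.DESIGN_COLUMNS)
        assert np.isnan(tab.loc[0, "p_value"])  # intercept p mirrors NA
        assert ((tab["p_value"].iloc[1:] >= 0) & (tab["p_value"].iloc[1:] <= 1)).all()
        assert fit.sigma2_taxon >= 0 and fit.sigma2_resid > 0

    def test_rank_deficient_names_columns(self):
        taxa, treatments, X = balanced_layout(3)
        X = X.copy()
        X["T1D_copy"] = X["T1D"]
        with pytest.raises(DesignMatrixError, match="collinear"):
            pv.fit_reml(np.ones(len(taxa)), X, taxa)

    def test_needs_two_groups(self):
        X = pv.build_design_matrix(pv.TREATMENTS)
        with pytest.raises(ValidationError):
            pv.fit_reml(np.ones(9), X, ["g0"] * 9)


class TestTreatmentMeansAndQuadrants:
    @staticmethod
    def fit_with_beta(beta):
        return LmmFit(
            terms=list(pv.DESIGN_COLUMNS), beta=np.asarray(beta, float),
            se=np.ones(9), p_wald=np.ones(9), sigma2_taxon=0.0, sigma2_resid=1.0,
            lambda_=0.0, reml_loglik=0.0, taxon_effects=pd.Series(dtype=float),
            n_obs=9, n_groups=2,
        )

    def test_published_coefficient_arithmetic(self):
        means = pv.treatment_means(self.fit_with_beta(TABLE_DIATOM_BETA))
        assert means["AA"] == pytest.approx(1.251)
        assert means["DA"] == pytest.approx(1.251 - 0.156)
        assert means["DD"] == pytest.approx(1.251 - 0.156 - 0.230 + 0.207)

    def test_quadrant_rules(self):
        x = {t: v for t, v in zip(pv.TREATMENTS, range(1, 10))}
        y = {t: v for t, v in zip(pv.TREATMENTS, range(9, 0, -1))}
        quad = pv.quadrant_classification(x, y)
        gx, gy = 5, 5
        for t in pv.TREATMENTS:
            ax, ay = x[t] >= gx, y[t] >= gy
            expect = "I" if ax and ay else "II" if not ax and ay else "III" if not ax and not ay else "IV"
            assert quad[t] == expect

    def test_all_equal_ties_go_above(self):
        x = {t: 1.0 for t in pv.TREATMENTS}
        quad = pv.quadrant_classification(x, dict(x))
        assert set(quad.values()) == {"I"}

    def test_reference_treatment_above_both_is_quadrant_one(self):
        x = {t: (2.0 if t == "AA" else 1.0) for t in pv.TREATMENTS}
        quad = pv.quadrant_classification(x, dict(x))
        assert quad["AA"] == "I"

    def test_key_mismatch(self):
        x = {t: 1.0 for t in pv.TREATMENTS}
        y = dict(x)
        y.pop("AA")
        with pytest.raises(ValidationError):
            pv.quadrant_classification(x, y)
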