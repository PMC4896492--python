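"""Mixed-effects topology models and collinearity screening."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gammatopo.topology import (
    REGION_AXES, center_coordinates, collinearity_screen, fit_lme,
    fit_region_models, topology_report, _profiled_reml,
)


def simulate_cell(rng, n_sub=10, per=6, beta=(0.3, 0.05, -0.02, 0.001),
                  subject_sd=0.4, resid_sd=0.3):
    subj = np.repeat(np.arange(n_sub), per)
    c = rng.uniform(-10, 10, size=(n_sub * per, 2))
    u = rng.normal(0, subject_sd, n_sub)
    y = (beta[0] + c[:, 0] * beta[1] + c[:, 1] * beta[2]
         + c[:, 0] * c[:, 1] * beta[3] + u[subj]
         + rng.normal(0, resid_sd, n_sub * per))
    return y, c, subj


def make_geometry(rng, n=30, region="VTC", hemi="L"):
    x = rng.uniform(-45, -25, n)
    y = rng.uniform(-75, -30, n)
    z = 5 - 0.5 * x + rng.normal(0, 1, n)
    return pd.DataFrame({"subject": [f"S{i % 5}" for i in range(n)],
                         "hemisphere": hemi, "region": region,
                         "x": x, "y": y, "z": z},
                        index=[f"e{i}" for i in range(n)])


class TestCentering:
    def test_centered_means_zero(self, rng):
        geo = pd.concat([make_geometry(rng, region="VTC"),
                         make_geometry(rng, region="LOC")])
        cent = center_coordinates(geo)
        for _, grp in cent.groupby(["hemisphere", "region"]):
            for ax in ("cx", "cy", "cz"):
                assert abs(grp[ax].mean()) < 1e-9

    def test_centering_invariance_of_slopes(self, rng):
        """Shifting raw coordinates before centering changes no estimate;
        without the interaction term a shift moves only the intercept."""
        y, c, subj = simulate_cell(rng)
        c0 = c - c.mean(axis=0)
        f1 = fit_lme(y, c0, subj)
        shifted = c + 123.4
        f2 = fit_lme(y, shifted - shifted.mean(axis=0), subj)
        assert np.allclose(f1.beta, f2.beta, atol=1e-8)
        f3 = fit_lme(y, c0, subj, add_interaction=False)
        f4 = fit_lme(y, c0 + 37.0, subj, add_interaction=False)
        assert np.allclose(f3.beta[1:], f4.beta[1:], atol=1e-8)


class TestCollinearityScreen:
    def test_monotone_pair_unit_correlation(self):
        n = 12
        geo = pd.DataFrame({"subject": "S0", "hemisphere": "R",
                            "region": "VTC",
                            "x": np.arange(n, dtype=float),
                            "y": np.linspace(0, 5, n),
                            "z": np.exp(np.linspace(0, 2, n))},
                           index=[f"e{i}" for i in range(n)])
        screen = collinearity_screen(geo)
        xz = screen[screen["pair"] == "x-z"].iloc[0]
        assert xz["spearman_r"] == pytest.approx(1.0)
        assert xz["dropped_axis"] == "z"

    def test_matches_rank_formula_oracle(self, rng):
        """Brute-force Spearman: Pearson correlation of the rank vectors."""
        geo = make_geometry(rng, n=25)
        screen = collinearity_screen(geo)
        for _, row in screen.iterrows():
            a, b = row["pair"].split("-")
            ra = stats.rankdata(geo[a])
            rb = stats.rankdata(geo[b])
            expected = np.corrcoef(ra, rb)[0, 1]
            assert row["spearman_r"] == pytest.approx(expected, abs=1e-10)

    def test_constant_coordinate_reported_nan(self, rng):
        geo = make_geometry(rng, n=10)
        geo["y"] = 3.0
        screen = collinearity_screen(geo)
        assert np.isnan(screen[screen["pair"] == "x-y"]["spearman_r"]).all()


class TestFitLME:
    def test_zero_subject_variance_reduces_to_ols(self):
        # residual subject-means removed: the REML variance-ratio estimate
        # must land on the zero boundary and the fit collapse to OLS
        local = np.random.default_rng(31)
        subj = np.repeat(np.arange(8), 10)
        c = local.uniform(-10, 10, size=(80, 2))
        resid = local.normal(0, 0.3, 80)
        resid -= np.repeat(resid.reshape(8, 10).mean(axis=1), 10)
        y = 0.3 + 0.05 * c[:, 0] - 0.02 * c[:, 1] + resid
        fit = fit_lme(y, c, subj)
        assert fit.boundary
        X = np.column_stack([np.ones(y.size), c[:, 0], c[:, 1],
                             c[:, 0] * c[:, 1]])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta, ols, rtol=1e-6, atol=1e-6)

    def test_matches_statsmodels_mixedlm(self, rng):
        """Independent engine cross-check on the same data."""
        import statsmodels.formula.api as smf
        y, c, subj = simulate_cell(rng)
        fit = fit_lme(y, c, subj)
        df = pd.DataFrame({"y": y, "c1": c[:, 0], "c2": c[:, 1], "g": subj})
        m = smf.mixedlm("y ~ c1 + c2 + c1:c2", df, groups="g").fit(reml=True)
        sm_order = [m.fe_params["Intercept"], m.fe_params["c1"],
                    m.fe_params["c2"], m.fe_params["c1:c2"]]
        assert np.allclose(fit.beta, sm_order, rtol=1e-5, atol=1e-7)
        assert fit.sigma2_resid == pytest.approx(m.scale, rel=1e-4)
        assert fit.sigma2_subject == pytest.approx(m.cov_re.values[0, 0],
                                                   rel=1e-3, abs=1e-6)

    def test_parameter_recovery(self, rng):
        """Mean estimates across replicates land within 2 SE of truth."""
        beta = (0.3, 0.05, -0.02, 0.001)
        est = []
        ses = []
        for _ in range(30):
            y, c, subj = simulate_cell(rng, n_sub=16, per=6, beta=beta,
                                       subject_sd=0.3)
            f = fit_lme(y, c, subj)
            est.append(f.beta)
            ses.append(f.se)
        mean_est = np.mean(est, axis=0)
        mean_se = np.mean(ses, axis=0) / np.sqrt(len(est))
        assert np.all(np.abs(mean_est - np.array(beta)) < 2 * np.sqrt(30) * mean_se)

    def test_reml_optimum_beats_grid(self, rng):
        """Optimizer sanity: returned ratio at least as good as a grid."""
        y, c, subj = simulate_cell(rng)
        fit = fit_lme(y, c, subj)
        lam_hat = fit.sigma2_subject / fit.sigma2_resid
        X = np.column_stack([np.ones(y.size), c[:, 0], c[:, 1],
                             c[:, 0] * c[:, 1]])
        order = np.argsort(subj, kind="stable")
        sizes = np.unique(subj[order], return_counts=True)[1]
        best = _profiled_reml(lam_hat, X[order], y[order], sizes)[0]
        for lam in np.linspace(0, 10, 50):
            assert best <= _profiled_reml(lam, X[order], y[order], sizes)[0] + 1e-7

    def test_one_electrode_per_subject_flagged(self, rng):
        y, c, subj = simulate_cell(rng, n_sub=30, per=1)
        fit = fit_lme(y, c, subj)
        assert fit.degenerate and fit.boundary

    def test_singular_design_names_columns(self, rng):
        n = 40
        c = np.column_stack([np.arange(n, dtype=float),
                             2.0 * np.arange(n, dtype=float)])
        with pytest.raises(ValueError, match="collinear"):
            fit_lme(rng.standard_normal(n), c, np.repeat(np.arange(8), 5))

    def test_satterthwaite_df_bracketed(self, rng):
        """Intercept df near n_subjects-1; slope df near residual df."""
        y, c, subj = simulate_cell(rng, n_sub=12, per=8, subject_sd=0.8)
        fit = fit_lme(y, c, subj)
        assert 5 < fit.df[0] < 20
        assert 40 < fit.df[1] <= 92


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(7)
    rows = []
    for e in range(60):
        hemi = "L" if e < 40 else "R"
        geo = {"x": rng.uniform(-45, -25) if hemi == "L" else rng.uniform(25, 45),
               "y": rng.uniform(-75, -30), "z": rng.uniform(-25, 0)}
        for cat in ["face", "animate", "place", "tool", "word"]:
            if cat == "word" and hemi != "L":
                continue
            d = rng.normal(0.05 * abs(geo["x"]) if cat == "face" else 0.0, 0.4)
            rows.append({"electrode": f"e{e}", "subject": f"S{e % 8}",
                         "hemisphere": hemi, "region": "VTC",
                         "x": geo["x"], "y": geo["y"], "z": geo["z"],
                         "category": cat, "d_prime": d,
                         "p_perm": 0.5, "fdr_flag": d > 1.0})
    return pd.DataFrame(rows)


class TestTopologyReport:

    def test_word_models_left_hemisphere_only(self, fitted):
        fits = fit_region_models(fitted)
        word = [f for f in fits if f.category == "word"]
        assert word and all(f.hemisphere == "L" for f in word)

    def test_sign_recovery_of_planted_gradient(self):
        """Fitted slope sign matches the planted |x| gradient direction."""
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            rows = []
            for e in range(50):
                x = rng.uniform(25, 45)
                y_c = rng.uniform(-75, -30)
                d = 0.06 * x + rng.normal(0, 0.5)
                rows.append({"electrode": f"e{e}", "subject": f"S{e % 8}",
                             "hemisphere": "R", "region": "VTC",
                             "x": x, "y": y_c, "z": 0.0, "category": "face",
                             "d_prime": d, "p_perm": 0.5, "fdr_flag": False})
            fits = fit_region_models(pd.DataFrame(rows))
            slope = fits[0].beta[fits[0].terms.index("x")]
            hits += slope > 0
        assert hits >= 19

    def test_counts_and_missing_cells(self, fitted):
        fits = fit_region_models(fitted)
        coeffs, counts = topology_report(fits, fitted,
                                         boundary_mm={"VTC": ("x", 0.0)})
        # words never flagged in RH: no word/R row at all
        assert not ((counts["category"] == "word")
                    & (counts["hemisphere"] == "R")).any()
        assert {"term", "estimate", "se", "p", "n_obs"} <= set(coeffs.columns)
        if len(counts):
            assert (counts["n_below_boundary"]
                    + counts["n_above_boundary"]).equals(counts["n_significant"])
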