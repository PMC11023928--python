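import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
import statsmodels.api as sm

import camtrap_pairs as cp
from camtrap_pairs.inference import LMMSpec, mvt_adjust, select_model

from conftest import balanced_rate_table, truth_effort


@pytest.fixture(scope="module")
def balanced():
    return balanced_rate_table(n_pairs=4, n_cameras=3, effect=0.3, seed=1)


def test_balanced_fit_equals_ols_coefficients(balanced):
    """Balanced nested design: GLS and OLS fixed effects coincide exactly."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = cp.fit_lmm(balanced, LMMSpec(), compute_ml_bic=False)
    X = sm.add_constant(balanced["certified"].astype(int).to_numpy())
    ols = sm.OLS(balanced["encounter_rate"].to_numpy(), X).fit()
    assert np.abs(fit.params.to_numpy() - ols.params).max() < 1e-8


def test_group_means_recovered_in_balanced_data(balanced):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = cp.fit_lmm(balanced, LMMSpec(), compute_ml_bic=False)
    m1 = balanced.loc[balanced["certified"], "encounter_rate"].mean()
    m0 = balanced.loc[~balanced["certified"], "encounter_rate"].mean()
    assert fit.params["Intercept"] == pytest.approx(m0, abs=1e-8)
    assert fit.params["cert"] == pytest.approx(m1 - m0, abs=1e-8)


def test_pair_collapsed_model_matches_paired_t_test():
    rng = np.random.default_rng(7)
    rows = []
    for p in range(7):
        base = rng.normal(1.0, 0.3)
        for cert in (True, False):
            rows.append(
                dict(
                    encounter_rate=base + (0.2 if cert else 0) + rng.normal(0, 0.15),
                    certified=cert,
                    pair_id=f"P{p}",
                    concession_id=f"P{p}{'F' if cert else 'N'}",
                    camera_id=f"P{p}{'F' if cert else 'N'}",
                )
            )
    df = pd.DataFrame(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = cp.fit_lmm(df, LMMSpec(), compute_ml_bic=False)
        cs = cp.certification_ratios(fit)
    x1 = df[df.certified].sort_values("pair_id")["encounter_rate"].to_numpy()
    x0 = df[~df.certified].sort_values("pair_id")["encounter_rate"].to_numpy()
    tt = st.ttest_rel(x1, x0)
    assert cs.df == 6.0
    assert cs.table["t"].iloc[0] == pytest.approx(tt.statistic, rel=1e-3)
    assert cs.table["p_raw"].iloc[0] == pytest.approx(tt.pvalue, rel=1e-3)


def test_variance_components_nonnegative_and_bic_formula(balanced):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = cp.fit_lmm(balanced, LMMSpec(), reml=False)
    assert all(v >= 0 for v in fit.vcomps.values())
    assert fit.bic == pytest.approx(-2 * fit.llf_ml + fit.k_params * np.log(fit.n_obs))


def test_reml_optimum_is_local_maximum(balanced):
    from statsmodels.regression.mixed_linear_model import MixedLMParams

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = cp.fit_lmm(balanced, LMMSpec(), compute_ml_bic=False)
    res = fit.result
    model = res.model
    base = res.params_object
    ll0 = model.loglike(base, profile_fe=True)
    for bump in (0.5, 2.0):
        pert = MixedLMParams.from_components(
            fe_params=res.fe_params,
            cov_re=np.atleast_2d(res.cov_re) * bump + 1e-4,
            vcomp=res.vcomp * bump + 1e-4,
        )
        assert model.loglike(pert, profile_fe=True) <= ll0 + 1e-6


def test_rank_deficient_design_errors(balanced):
    df = balanced.assign(dup=balanced["certified"].astype(int))
    with pytest.raises(ValueError, match="rank deficient"):
        cp.fit_lmm(df, LMMSpec(covariates=("dup",)))


def test_needs_two_pairs(balanced):
    df = balanced[balanced["pair_id"] == "P0"]
    with pytest.raises(ValueError, match="2 concession pairs"):
        cp.fit_lmm(df, LMMSpec())


def test_certification_ratio_is_ratio_of_marginal_means():
    df = balanced_rate_table(n_pairs=4, n_cameras=2, effect=0.0, sd=0.0, seed=0)
    df["encounter_rate"] = np.where(df["certified"], 0.30, 0.20)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = cp.fit_lmm(df, LMMSpec(), compute_ml_bic=False)
        cs = cp.certification_ratios(fit)
    assert cs.table["ratio"].iloc[0] == pytest.approx(1.5, abs=1e-6)
    df2 = df.assign(encounter_rate=0.25)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit2 = cp.fit_lmm(df2, LMMSpec(), compute_ml_bic=False)
        cs2 = cp.certification_ratios(fit2)
    assert cs2.table["ratio"].iloc[0] == pytest.approx(1.0, abs=1e-6)


def test_log1p_transform_ratio_on_response_scale():
    df = balanced_rate_table(n_pairs=4, n_cameras=2, effect=0.0, sd=0.0, seed=0)
    df["encounter_rate"] = np.where(df["certified"], 0.30, 0.20)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = cp.fit_lmm(df, LMMSpec(transform="log1p"), compute_ml_bic=False)
        cs = cp.certification_ratios(fit)
    assert cs.table["ratio"].iloc[0] == pytest.approx(1.5, abs=1e-6)


def test_mvt_adjust_identity_for_single_contrast():
    p, se = mvt_adjust([2.0], np.eye(1), df=10)
    assert p[0] == pytest.approx(2 * st.t.sf(2.0, 10))
    assert se == 0.0


def test_mvt_adjust_independence_closed_form():
    t = 2.0
    df = 2000.0
    p, mc_se = mvt_adjust([t, t], np.eye(2), df=df, n_mc=2**17, seed=3)
    p_raw = 2 * st.t.sf(t, df)
    expected = 1 - (1 - p_raw) ** 2
    assert p[0] == pytest.approx(expected, abs=max(5 * mc_se, 2e-3))


def test_mvt_adjust_perfect_correlation_degenerates_to_raw():
    R = np.ones((2, 2))
    p, mc_se = mvt_adjust([2.0, 2.0], R, df=50, n_mc=2**16, seed=0)
    p_raw = 2 * st.t.sf(2.0, 50)
    # max of two perfectly correlated |T|s is just |T|
    assert np.allclose(p, p_raw, atol=max(5 * mc_se, 2e-3))


def test_mvt_adjust_bounds_and_monotonicity():
    rng = np.random.default_rng(0)
    for _ in range(10):
        m = rng.integers(2, 6)
        A = rng.normal(size=(m, m + 2))
        C = A @ A.T
        d = np.sqrt(np.diag(C))
        R = C / np.outer(d, d)
        t = rng.normal(scale=2.0, size=m)
        df = float(rng.integers(4, 40))
        p, _ = mvt_adjust(t, R, df=df, n_mc=2**13, seed=1)
        p_raw = 2 * st.t.sf(np.abs(t), df)
        assert (p >= p_raw - 1e-12).all()
        assert (p <= np.minimum(1.0, m * p_raw) + 1e-12).all()
        order = np.argsort(-np.abs(t))
        assert (np.diff(p[order]) >= -1e-12).all()


def test_mvt_adjust_invalid_inputs():
    with pytest.raises(ValueError):
        mvt_adjust([], np.eye(0), df=5)
    with pytest.raises(ValueError):
        mvt_adjust([1.0, 1.0], np.array([[1.0, 2.0], [2.0, 1.0]]), df=5)
    with pytest.raises(ValueError):
        mvt_adjust([1.0], np.eye(1), df=-1)


def test_select_model_no_candidates_returns_base():
    df = balanced_rate_table(n_pairs=3, n_cameras=4, seed=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spec, table = select_model(df, [], LMMSpec())
    assert spec.covariates == ()
    assert len(table) == 1


def _covariate_survey(seed, slope):
    design = cp.SimDesign(
        n_pairs=3, cameras_per_concession=(8, 8), deployment_days=40,
        sd_pair=0.2, sd_concession=0.15, sd_camera=0.3,
        covariate_effects={"elevation": slope}, seed=seed,
    )
    species = [
        cp.SpeciesSpec("blue duiker", 4.5, "LC", "ungulates", base_rate=0.8)
    ]
    ev, dep, traits_raw = cp.simulate_events(species, design, np.random.default_rng(seed))
    traits = cp.load_traits(traits_raw)
    eff = truth_effort(dep)
    tab = cp.encounter_rate(ev, eff, traits, level="all", unit="camera")
    return tab.merge(dep[["camera_id", "elevation", "dist_rivers"]], on="camera_id")


@pytest.mark.parametrize("slope, expect_selected, min_frac", [(0.6, True, 0.8), (0.0, False, 0.5)])
def test_select_model_bic_consistency(slope, expect_selected, min_frac):
    """A strong covariate effect is selected; under the null the base model wins."""
    hits = 0
    n_rep = 40
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_rep):
            tab = _covariate_survey(3000 + i, slope)
            spec, _ = select_model(
                tab, ["elevation", "dist_rivers"], LMMSpec(), allow_quadratic=False
            )
            selected = "elevation" in spec.covariates
            if expect_selected:
                hits += selected
            else:
                hits += spec.covariates == ()
    assert hits / n_rep > min_frac
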