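"""Nested mixed-effects inference for the paired certification design.

The response is the camera-level encounter rate.  Certification status is a
concession-level treatment inside a blocked design, so the model carries
random intercepts for concession pair, concession-within-pair and (when a
camera contributes several rows, as in the group-wise analyses)
camera-within-concession:

    rate ~ certification (+ group + certification:group + covariates)
           + (1 | pair) + (1 | pair:concession) + (1 | concession:camera)

Fitting is delegated to :class:`statsmodels` ``MixedLM`` with the pair as
the top-level group and the lower levels as variance components.  REML is
used for reported fits and ML likelihoods for BIC-based covariate
selection.  Certification contrasts use containment degrees of freedom
(``n_concessions - n_pairs - 1``): the treatment varies between
concessions within pairs, so camera-level replication must not inflate the
test.  Families of per-group contrasts are adjusted with a multivariate-t
max-|T| procedure that respects the contrasts' estimated correlation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import patsy
import scipy.stats as st
from scipy.stats import qmc
import statsmodels.formula.api as smf

__all__ = [
    "LMMSpec",
    "LMMFit",
    "ContrastSet",
    "standardize",
    "fit_lmm",
    "select_model",
    "mvt_adjust",
    "certification_ratios",
]

RESPONSE_TRANSFORMS = ("identity", "log1p")


@dataclass(frozen=True)
class LMMSpec:
    """Model specification for the certification analysis.

    ``group_col`` (e.g. ``"group_label"``) requests a status-by-group
    interaction so each group gets its own certification contrast.
    ``covariates`` are camera-level numeric columns (standardize first);
    names in ``quadratic`` additionally enter squared.
    """

    transform: str = "identity"
    group_col: str | None = None
    covariates: tuple[str, ...] = ()
    quadratic: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.transform not in RESPONSE_TRANSFORMS:
            raise ValueError(f"transform must be one of {RESPONSE_TRANSFORMS}")
        unknown = set(self.quadratic) - set(self.covariates)
        if unknown:
            raise ValueError(f"quadratic terms must be among covariates: {sorted(unknown)}")

    @property
    def fixed_formula(self) -> str:
        terms = []
        if self.group_col:
            terms.append(f"C({self.group_col}) * cert")
        else:
            terms.append("cert")
        for c in self.covariates:
            terms.append(c)
            if c in self.quadratic:
                terms.append(f"I({c} ** 2)")
        return "y ~ " + " + ".join(terms)

    @property
    def n_fixed_terms(self) -> int:
        return len(self.covariates) + len(self.quadratic)


@dataclass
class LMMFit:
    """A fitted certification model plus the metadata inference needs."""

    spec: LMMSpec
    params: pd.Series
    cov_params: pd.DataFrame
    vcomps: dict
    llf: float
    reml: bool
    llf_ml: float | None
    bic: float | None
    n_obs: int
    k_params: int
    n_pairs: int
    n_concessions: int
    groups: tuple
    converged: bool
    singular: bool
    design_info: object = field(repr=False, default=None)
    covariate_means: dict = field(default_factory=dict)
    result: object = field(repr=False, default=None)  # statsmodels MixedLMResults

    @property
    def contrast_df(self) -> float:
        """Containment degrees of freedom for certification contrasts."""
        return float(self.n_concessions - self.n_pairs - 1)

    def summary_dict(self) -> dict:
        return {
            "transform": self.spec.transform,
            "fixed_effects": {k: float(v) for k, v in self.params.items()},
            "variance_components": {k: float(v) for k, v in self.vcomps.items()},
            "loglik": float(self.llf),
            "reml": self.reml,
            "loglik_ml": None if self.llf_ml is None else float(self.llf_ml),
            "bic": None if self.bic is None else float(self.bic),
            "n_obs": self.n_obs,
            "n_pairs": self.n_pairs,
            "n_concessions": self.n_concessions,
            "converged": self.converged,
            "singular": self.singular,
        }


@dataclass
class ContrastSet:
    """Per-group certification contrasts with multiplicity adjustment."""

    table: pd.DataFrame
    correlation: pd.DataFrame
    df: float
    n_mc: int
    seed: int
    mc_se: float


def standardize(data: pd.DataFrame, cols) -> pd.DataFrame:
    """Z-score ``cols`` in a copy of ``data`` (constant columns become 0)."""
    out = data.copy()
    for c in cols:
        x = out[c].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"covariate {c!r} contains non-finite values")
        sd = x.std()
        out[c] = (x - x.mean()) / sd if sd > 0 else 0.0
    return out


def _prepare(data: pd.DataFrame, spec: LMMSpec) -> pd.DataFrame:
    req = {"encounter_rate", "certified", "pair_id", "concession_id"}
    missing = req - set(data.columns)
    if missing:
        raise ValueError(f"rate table is missing columns: {sorted(missing)}")
    df = data.copy()
    y = df["encounter_rate"].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("encounter_rate contains non-finite values")
    df["y"] = np.log1p(y) if spec.transform == "log1p" else y
    df["cert"] = df["certified"].astype(bool).astype(int)
    for c in spec.covariates:
        if not np.all(np.isfinite(df[c].to_numpy(dtype=float))):
            raise ValueError(f"covariate {c!r} contains non-finite values")
    return df


def _check_rank(df: pd.DataFrame, spec: LMMSpec) -> None:
    X = patsy.dmatrix(spec.fixed_formula.split("~", 1)[1], df, return_type="dataframe")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"fixed-effect design is rank deficient ({rank} < {X.shape[1]}); "
            f"columns: {list(X.columns)}"
        )


def fit_lmm(
    data: pd.DataFrame,
    spec: LMMSpec = LMMSpec(),
    reml: bool = True,
    compute_ml_bic: bool = True,
) -> LMMFit:
    """Fit the nested certification model to a camera-level rate table.

    ``data`` needs columns ``encounter_rate, certified, pair_id,
    concession_id`` plus ``camera_id`` (and the spec's group/covariate
    columns).  The camera variance component is only estimable when cameras
    contribute more than one row (group-wise analyses); with one row per
    camera it is aliased with the residual and dropped.  Variance
    components shrinking to the zero boundary are flagged ``singular`` but
    not fatal.  ``compute_ml_bic`` additionally fits by ML to attach a BIC
    (``-2 logL_ML + k log n``).
    """
    df = _prepare(data, spec)
    n_pairs = df["pair_id"].nunique()
    if n_pairs < 2:
        raise ValueError("need at least 2 concession pairs")
    _check_rank(df, spec)

    vc = {}
    if df.groupby("pair_id")["concession_id"].nunique().max() < 2:
        warnings.warn("single concession per pair; concession component dropped", stacklevel=2)
    elif df.groupby("concession_id")["y"].size().max() > 1:
        vc["concession"] = "0 + C(concession_id)"
    # a level with one row per unit is aliased with the residual and dropped
    multi_row_cameras = (
        "camera_id" in df.columns and df.groupby("camera_id")["y"].size().max() > 1
    )
    if multi_row_cameras:
        vc["camera"] = "0 + C(camera_id)"

    model = smf.mixedlm(
        spec.fixed_formula,
        df,
        groups="pair_id",
        re_formula="1",
        vc_formula=vc or None,
    )

    def _fit(use_reml):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in ("lbfgs", "bfgs", "powell"):
                try:
                    res = model.fit(reml=use_reml, method=method, maxiter=500)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if res.converged:
                    return res
            return res  # last attempt, possibly unconverged

    res = _fit(reml)
    k_fixed = len(res.fe_params)
    k_var = 1 + len(vc) + 1  # pair + components + residual
    k = k_fixed + k_var

    llf_ml = bic = None
    if compute_ml_bic:
        res_ml = res if not reml else _fit(False)
        llf_ml = float(res_ml.llf)
        bic = -2.0 * llf_ml + k * np.log(len(df))

    vcomps = {"pair": float(np.asarray(res.cov_re).ravel()[0])}
    for name in vc:
        vcomps[name] = float(res.vcomp[list(vc).index(name)])
    vcomps["resid"] = float(res.scale)
    tol = 1e-6 * max(vcomps["resid"], 1e-12)
    singular = any(v <= tol for kk, v in vcomps.items() if kk != "resid")

    fe_names = list(res.fe_params.index)
    return LMMFit(
        spec=spec,
        params=res.fe_params,
        cov_params=res.cov_params().loc[fe_names, fe_names],
        vcomps=vcomps,
        llf=float(res.llf),
        reml=reml,
        llf_ml=llf_ml,
        bic=bic,
        n_obs=len(df),
        k_params=k,
        n_pairs=n_pairs,
        n_concessions=df["concession_id"].nunique(),
        groups=tuple(sorted(df[spec.group_col].unique())) if spec.group_col else ("all",),
        converged=bool(res.converged),
        singular=singular,
        design_info=model.data.design_info,
        covariate_means={c: float(df[c].mean()) for c in spec.covariates},
        result=res,
    )


def select_model(
    data: pd.DataFrame,
    candidates,
    base_spec: LMMSpec = LMMSpec(),
    allow_quadratic: bool = True,
    max_exhaustive: int = 2,
    forward: bool = True,
) -> tuple[LMMSpec, pd.DataFrame]:
    """BIC-minimizing search over covariate subsets.

    Candidates are z-scored before fitting; ML likelihoods are compared.
    All subsets up to ``max_exhaustive`` covariates (optionally with
    quadratic terms) are fitted exhaustively; if more candidates remain,
    the search continues forward from the best subset while BIC improves.
    Ties break toward fewer parameters.  Returns the winning spec and the
    full BIC table.
    """
    candidates = list(candidates)
    df = standardize(data, candidates)
    rows = []
    seen = {}

    def eval_spec(spec):
        key = (tuple(sorted(spec.covariates)), tuple(sorted(spec.quadratic)))
        if key in seen:
            return seen[key]
        fit = fit_lmm(df, spec, reml=False, compute_ml_bic=True)
        seen[key] = (spec, fit.bic, fit.k_params)
        rows.append(
            {
                "covariates": "+".join(spec.covariates) or "(none)",
                "quadratic": "+".join(spec.quadratic) or "",
                "k_params": fit.k_params,
                "loglik_ml": fit.llf_ml,
                "bic": fit.bic,
            }
        )
        return seen[key]

    def specs_for(subset):
        out = []
        if allow_quadratic:
            for r in range(len(subset) + 1):
                for q in itertools.combinations(subset, r):
                    out.append(replace(base_spec, covariates=tuple(subset), quadratic=q))
        else:
            out.append(replace(base_spec, covariates=tuple(subset), quadratic=()))
        return out

    best = eval_spec(replace(base_spec, covariates=(), quadratic=()))
    for r in range(1, min(max_exhaustive, len(candidates)) + 1):
        for subset in itertools.combinations(candidates, r):
            for spec in specs_for(subset):
                cand = eval_spec(spec)
                if _better(cand, best):
                    best = cand

    if forward and len(candidates) > max_exhaustive:
        improved = True
        while improved:
            improved = False
            current = set(best[0].covariates)
            for c in candidates:
                if c in current:
                    continue
                subset = tuple(sorted(current | {c}))
                for q in ([(), (c,)] if allow_quadratic else [()]):
                    quad = tuple(sorted(set(best[0].quadratic) | set(q)))
                    cand = eval_spec(replace(base_spec, covariates=subset, quadratic=quad))
                    if _better(cand, best):
                        best, improved = cand, True

    table = pd.DataFrame(rows).sort_values("bic", kind="mergesort").reset_index(drop=True)
    return best[0], table


def _better(cand, best):
    # lower BIC wins; ties (within 1e-9) go to fewer parameters
    if cand[1] < best[1] - 1e-9:
        return True
    if abs(cand[1] - best[1]) <= 1e-9 and cand[2] < best[2]:
        return True
    return False


def mvt_adjust(
    t_values,
    correlation,
    df: float,
    n_mc: int = 100_000,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Max-|T| multivariate-t adjusted p-values.

    For contrasts with joint t distribution (dimension m, correlation R,
    df nu), the adjusted p-value of contrast i is
    ``P(max_j |T_j| >= |t_i|)`` estimated by quasi-Monte-Carlo (scrambled
    Sobol).  Estimates are clamped to the exact bounds
    ``p_raw <= p_adj <= min(1, m * p_raw)``.  Returns ``(p_adj, mc_se)``
    where ``mc_se`` is the worst-case Monte-Carlo standard error.
    """
    t_values = np.atleast_1d(np.asarray(t_values, dtype=float))
    m = len(t_values)
    if m == 0:
        raise ValueError("no contrasts to adjust")
    if df <= 0:
        raise ValueError("df must be positive")
    p_raw = 2.0 * st.t.sf(np.abs(t_values), df)
    if m == 1:
        return p_raw, 0.0

    R = np.asarray(correlation, dtype=float)
    if R.shape != (m, m) or not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation must be a symmetric m x m matrix")
    if not np.allclose(np.diag(R), 1.0, atol=1e-6):
        raise ValueError("correlation must have unit diagonal")
    w, V = np.linalg.eigh(R)
    if w.min() < -1e-8:
        raise ValueError("correlation matrix is not positive semi-definite")
    L = V * np.sqrt(np.clip(w, 0.0, None))

    sampler = qmc.Sobol(d=m + 1, scramble=True, seed=seed)
    u = sampler.random_base2(int(np.ceil(np.log2(n_mc))))  # power of 2 >= n_mc
    u = np.clip(u, 1e-12, 1 - 1e-12)
    z = st.norm.ppf(u[:, :m]) @ L.T
    chi = st.chi2.ppf(u[:, m], df) / df
    max_abs_t = np.abs(z).max(axis=1) / np.sqrt(chi)

    p_adj = np.array([(max_abs_t >= abs(t)).mean() for t in t_values])
    mc_se = float(np.sqrt(np.max(p_adj * (1 - p_adj)) / n_mc))
    p_adj = np.minimum(np.maximum(p_adj, p_raw), np.minimum(1.0, m * p_raw))
    return p_adj, mc_se


def _emm_rows(fit: LMMFit, group, cert: int) -> np.ndarray:
    """Design row for the estimated marginal mean of (group, status)."""
    newdata = {"cert": [cert]}
    if fit.spec.group_col:
        newdata[fit.spec.group_col] = [group]
    for c, mean in fit.covariate_means.items():
        newdata[c] = [mean]
    (X,) = patsy.build_design_matrices([fit.design_info], pd.DataFrame(newdata))
    return np.asarray(X)[0]


def certification_ratios(
    fit: LMMFit,
    n_mc: int = 100_000,
    seed: int = 0,
) -> ContrastSet:
    """Certification contrasts and response-scale rate ratios per group.

    For each group the estimated marginal means (EMMs) of certified and
    non-certified concessions are formed at covariate means; the contrast
    (difference on the model scale) is tested with containment df and the
    family is max-|T| adjusted.  The ratio EMM_certified / EMM_noncert is
    reported on the response scale with a delta-method standard error; a
    non-positive denominator makes the ratio undefined (NaN, flagged).
    """
    beta = fit.params.to_numpy()
    Sigma = fit.cov_params.to_numpy()
    df_t = fit.contrast_df
    if df_t <= 0:
        raise ValueError("non-positive containment df; need more concessions than pairs + 1")

    rows = []
    Lmat = []
    for g in fit.groups:
        x1 = _emm_rows(fit, g, 1)
        x0 = _emm_rows(fit, g, 0)
        Lmat.append(x1 - x0)
        mu1_lin, mu0_lin = float(x1 @ beta), float(x0 @ beta)
        if fit.spec.transform == "log1p":
            mu1, mu0 = np.expm1(mu1_lin), np.expm1(mu0_lin)
            g1, g0 = np.exp(mu1_lin) * x1, np.exp(mu0_lin) * x0
        else:
            mu1, mu0 = mu1_lin, mu0_lin
            g1, g0 = x1, x0
        if mu0 > 0 and mu1 > 0:
            ratio = mu1 / mu0
            grad = g1 / mu0 - (mu1 / mu0**2) * g0
            ratio_se = float(np.sqrt(grad @ Sigma @ grad))
        else:
            ratio, ratio_se = np.nan, np.nan
        rows.append({"group": g, "emm_certified": mu1, "emm_noncert": mu0,
                     "ratio": ratio, "ratio_se": ratio_se})

    Lmat = np.asarray(Lmat)
    est = Lmat @ beta
    C = Lmat @ Sigma @ Lmat.T
    se = np.sqrt(np.diag(C))
    corr = C / np.outer(se, se)
    tstat = est / se
    p_adj, mc_se = mvt_adjust(tstat, corr, df_t, n_mc=n_mc, seed=seed)

    table = pd.DataFrame(rows)
    table["estimate"] = est
    table["se"] = se
    table["df"] = df_t
    table["t"] = tstat
    table["p_raw"] = 2.0 * st.t.sf(np.abs(tstat), df_t)
    table["p_adj"] = p_adj
    corr_df = pd.DataFrame(corr, index=fit.groups, columns=fit.groups)
    return ContrastSet(table=table, correlation=corr_df, df=df_t,
                       n_mc=n_mc, seed=seed, mc_se=mc_se)
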