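"""Longitudinal linear mixed models, marginal means, and Tukey contrasts.

Each cortical index is modelled with a linear mixed model: categorical fixed
effects (time bin, stimulation condition, side of auditory cortex and their
interactions), the two study covariates (age at first implantation and
inter-implant delay, always included), and a random intercept per
participant, fitted by restricted maximum likelihood. Factors use
sum-to-zero coding so Wald F tests of term blocks are Type-III-like.

Denominator degrees of freedom use a between-within (containment)
approximation — exact for balanced designs and recorded as the method label
in every table; estimated marginal means average model predictions over the
other factors with covariates held at their sample means, and pairwise
contrasts carry Tukey (studentized-range) family-wise adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sstats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ModelSpec",
    "ModelFit",
    "EmmTable",
    "fit_lmm",
    "anova_table",
    "estimated_marginal_means",
    "pairwise_contrasts",
    "fit_predictor_model",
]

DF_METHOD = "between-within"


@dataclass
class ModelSpec:
    """Fixed/random structure of one mixed model.

    ``fixed`` lists factor terms (e.g. ``["time_bin", "condition",
    "time_bin:condition"]``); the study covariates and the per-participant
    random intercept are always included.
    """

    response: str
    fixed: list
    covariates: tuple = ("age_ci1", "inter_implant_delay")
    groups: str = "participant_id"

    def formula(self) -> str:
        def enc(term):
            return ":".join(f"C({f}, Sum)" for f in term.split(":"))
        rhs = [enc(t) for t in self.fixed] + list(self.covariates)
        return f"{self.response} ~ " + " + ".join(rhs)

    def columns(self) -> list:
        cols = {self.response, self.groups, *self.covariates}
        for t in self.fixed:
            cols.update(t.split(":"))
        return sorted(cols)


@dataclass
class ModelFit:
    """A fitted mixed model plus bookkeeping for tables and contrasts."""

    spec: ModelSpec
    result: object
    data: pd.DataFrame
    converged: bool
    n_dropped: int
    var_intercept: float
    var_residual: float
    df_method: str = DF_METHOD

    @property
    def fe_params(self) -> np.ndarray:
        return np.asarray(self.result.fe_params)

    @property
    def fe_cov(self) -> np.ndarray:
        k = len(self.result.fe_params)
        return np.asarray(self.result.cov_params())[:k, :k]

    @property
    def design_info(self):
        return self.result.model.data.design_info

    def n_obs(self) -> int:
        return len(self.data)

    def n_groups(self) -> int:
        return self.data[self.spec.groups].nunique()


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """REML fit of the mixed model; missing rows are dropped listwise.

    Raises on fewer than 2 participants with 2+ observations. A singular or
    non-converged optimisation is flagged (``converged=False``), never
    silently zeroed.
    """
    cols = spec.columns()
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise ValueError(f"data missing columns {missing_cols}")
    sub = data[cols].copy()
    n0 = len(sub)
    sub = sub.dropna()
    n_dropped = n0 - len(sub)
    counts = sub.groupby(spec.groups).size()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 participants with >= 2 observations each")

    model = smf.mixedlm(spec.formula(), sub, groups=sub[spec.groups])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = model.fit(reml=True, method="lbfgs", maxiter=200)
            converged = bool(result.converged)
        except Exception:
            result = model.fit(reml=True, method="powell", maxiter=500)
            converged = bool(result.converged)
    var_int = float(np.asarray(result.cov_re)[0, 0])
    return ModelFit(spec=spec, result=result, data=sub.reset_index(drop=True),
                    converged=converged, n_dropped=n_dropped,
                    var_intercept=var_int, var_residual=float(result.scale))


def _term_slices(fit: ModelFit):
    di = fit.design_info
    return {name: di.term_name_slices[name] for name in di.term_names
            if name != "Intercept"}


def _between_within_df(fit: ModelFit):
    """Containment denominator df per fixed term.

    A term is *between* when its design columns are constant within every
    participant (covariates such as age at CI-1 and delay); its F is tested
    against participants minus between-level parameters. Within terms are
    tested against the residual observations.
    """
    X = np.asarray(fit.result.model.exog)
    groups = fit.data[fit.spec.groups].to_numpy()
    _, ginv = np.unique(groups, return_inverse=True)
    n_groups = fit.n_groups()
    n_obs = fit.n_obs()

    col_between = np.ones(X.shape[1], dtype=bool)
    for g in range(n_groups):
        sel = ginv == g
        col_between &= np.ptp(X[sel], axis=0) < 1e-10

    q_between = int(col_between.sum())            # includes the intercept
    p_total = X.shape[1]
    ddf_between = max(n_groups - q_between, 1)
    ddf_within = max(n_obs - n_groups - (p_total - q_between), 1)

    out = {}
    for name, sl in _term_slices(fit).items():
        between = bool(col_between[sl].all())
        out[name] = ddf_between if between else ddf_within
    out["__within__"] = ddf_within
    out["__between__"] = ddf_between
    return out


def anova_table(fit: ModelFit) -> pd.DataFrame:
    """Type-III-style Wald F test per fixed term.

    Refuses non-converged fits. Significance is marked at the .05 level;
    the denominator-df method label is recorded per row.
    """
    if not fit.converged:
        raise RuntimeError("model did not converge; refusing to build tables")
    beta = fit.fe_params
    V = fit.fe_cov
    ddfs = _between_within_df(fit)
    rows = []
    for name, sl in _term_slices(fit).items():
        idx = np.arange(len(beta))[sl]
        if idx.size == 0:
            warnings.warn(f"term {name} has no estimable parameters; dropped")
            continue
        b = beta[idx]
        Vb = V[np.ix_(idx, idx)]
        try:
            F = float(b @ np.linalg.solve(Vb, b)) / idx.size
        except np.linalg.LinAlgError:
            warnings.warn(f"singular covariance for term {name}; dropped")
            continue
        ddf = ddfs[name]
        p = float(sstats.f.sf(F, idx.size, ddf))
        rows.append(dict(term=_pretty_term(name), F=F, df_num=idx.size,
                         df_den=ddf, p=p, significant=p < 0.05,
                         df_method=fit.df_method))
    return pd.DataFrame(rows)


def _pretty_term(name: str) -> str:
    return (name.replace("C(", "").replace(", Sum)", "")
            .replace(")", "").replace("(", ""))


def _reference_grid(fit: ModelFit, factors):
    """Cross of requested-factor levels × other-factor levels; covariate means."""
    data = fit.data
    model_factors = sorted({f for t in fit.spec.fixed for f in t.split(":")})
    for f in factors:
        if f not in model_factors:
            raise ValueError(f"factor {f!r} not in the model")
    for c in factors:
        if c in fit.spec.covariates:
            raise ValueError(f"{c!r} is a continuous covariate, not a factor")
    levels = {f: sorted(data[f].astype(str).unique()) for f in model_factors}
    from itertools import product
    rows = [dict(zip(model_factors, combo))
            for combo in product(*[levels[f] for f in model_factors])]
    grid = pd.DataFrame(rows)
    for c in fit.spec.covariates:
        grid[c] = float(data[c].mean())
    return grid, model_factors


@dataclass
class EmmTable:
    """Estimated marginal means with the L matrices that produced them."""

    table: pd.DataFrame
    L: np.ndarray
    factors: list
    fit: ModelFit


def estimated_marginal_means(fit: ModelFit, factors) -> EmmTable:
    """Marginal means per cell of ``factors``.

    Model predictions on the reference grid are averaged over the other
    factors with covariates at their sample means; standard errors come from
    the fitted fixed-effect covariance.
    """
    if not fit.converged:
        raise RuntimeError("model did not converge; refusing to build tables")
    factors = list(factors)
    grid, _ = _reference_grid(fit, factors)
    (X,) = patsy.build_design_matrices([fit.design_info], grid)
    X = np.asarray(X)
    beta = fit.fe_params
    V = fit.fe_cov
    ddf = _between_within_df(fit)["__within__"]

    cells = grid[factors].drop_duplicates().reset_index(drop=True)
    Ls, rows = [], []
    for _, cell in cells.iterrows():
        sel = np.ones(len(grid), dtype=bool)
        for f in factors:
            sel &= (grid[f] == cell[f]).to_numpy()
        L = X[sel].mean(axis=0)
        est = float(L @ beta)
        se = float(np.sqrt(max(L @ V @ L, 0.0)))
        row = {f: cell[f] for f in factors}
        row.update(emm=est, se=se, df=ddf)
        rows.append(row)
        Ls.append(L)
    return EmmTable(table=pd.DataFrame(rows), L=np.vstack(Ls),
                    factors=factors, fit=fit)


def pairwise_contrasts(emms: EmmTable, family: str | None = None) -> pd.DataFrame:
    """All pairwise EMM differences with Tukey family-wise adjustment.

    For two levels the adjusted p equals the unadjusted two-sided p; the
    adjusted p is never below the unadjusted one. Returns an empty frame for
    a single level.
    """
    tab = emms.table
    factors = emms.factors if family is None else [family]
    labels = tab[emms.factors].astype(str).agg(" ".join, axis=1).to_numpy()
    k = len(tab)
    if k < 2:
        return pd.DataFrame(columns=["contrast", "estimate", "se", "t",
                                     "df", "p_unadjusted", "p_tukey"])
    beta = emms.fit.fe_params
    V = emms.fit.fe_cov
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            L = emms.L[i] - emms.L[j]
            est = float(L @ beta)
            se = float(np.sqrt(max(L @ V @ L, 0.0)))
            df = float(tab["df"].iloc[i])
            t = est / se if se > 0 else np.inf
            p_un = 2.0 * float(sstats.t.sf(abs(t), df))
            p_tk = float(sstats.studentized_range.sf(
                abs(t) * np.sqrt(2.0), k, df))
            rows.append(dict(
                contrast=f"{labels[i]} - {labels[j]}", estimate=est, se=se,
                t=t, df=df, p_unadjusted=p_un,
                p_tukey=min(max(p_tk, p_un), 1.0),
                df_method=emms.fit.df_method))
    return pd.DataFrame(rows)


def fit_predictor_model(data: pd.DataFrame, outcome: str, predictors,
                        covariates=("age_ci1", "inter_implant_delay")):
    """Ordinary least squares with per-predictor F tests.

    Covaries for age at CI-1 and inter-implant delay by default. Raises on
    rank deficiency, naming the collinear columns.
    """
    predictors = list(predictors)
    cols = [outcome] + predictors + [c for c in covariates if c not in predictors]
    sub = data[cols].dropna()
    if len(sub) < len(predictors) + 2:
        raise ValueError("too few complete cases for the predictor model")
    rhs = " + ".join(predictors + [c for c in covariates if c not in predictors])
    model = smf.ols(f"{outcome} ~ {rhs}", sub)
    X = model.exog
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        bad = [model.exog_names[i] for i in range(X.shape[1])
               if np.linalg.matrix_rank(np.delete(X, i, axis=1)) == rank]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    result = model.fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(result, typ=2)
    return result, table
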