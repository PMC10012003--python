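"""Within/between-person multilevel analysis layer.

Implements the statistical toolkit for intensive longitudinal (daily diary)
data with days nested in participants:

* intraclass correlation coefficients from intercept-only ("empty") models,
  via a one-way random-effects ANOVA estimator valid for unbalanced data,
  with a REML alternative;
* random-intercept day-level association models with categorical or
  continuous predictors and demographic covariates (REML via statsmodels
  MixedLM);
* within/between decomposition models using person-mean centering;
* linear contrasts over factor levels with propagated standard errors;
* semipartial correlation effect sizes (correlation between the outcome and
  the portion of the focal predictor orthogonal to the other terms).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, SingularDesignError
from .prep import person_mean_center

__all__ = [
    "VarianceComponents",
    "ModelResult",
    "variance_components",
    "fit_day_level_model",
    "within_between_association",
    "contrast",
    "semipartial_r",
]


@dataclass(frozen=True)
class VarianceComponents:
    """Between/within variance decomposition from an empty model."""

    sigma2_between: float
    sigma2_within: float
    n_persons: int
    n_obs: int
    method: str = "anova"

    @property
    def icc(self) -> float:
        total = self.sigma2_between + self.sigma2_within
        return self.sigma2_between / total if total > 0 else 0.0


def variance_components(
    outcome: Sequence[float] | pd.Series,
    participant_ids: Sequence | pd.Series,
    method: str = "anova",
) -> VarianceComponents:
    """Empty-model variance decomposition for the ICC.

    The default is the one-way random-effects ANOVA estimator for unbalanced
    data: ``sigma2_within = MSW``, ``sigma2_between = max(0, (MSB - MSW) /
    n0)`` with ``n0 = (N - sum(n_i^2)/N) / (k - 1)``; negative between
    estimates truncate to zero.  ``method="reml"`` fits an intercept-only
    random-intercept model instead (the two agree closely on balanced data).
    """
    y = np.asarray(outcome, dtype=float)
    ids = np.asarray(participant_ids)
    if len(y) != len(ids):
        raise InvalidInputError("outcome and participant_ids differ in length")
    groups, counts = np.unique(ids, return_counts=True)
    k, n_total = len(groups), len(y)
    if k < 2:
        raise InvalidInputError("need >= 2 participants for variance components")
    if counts.max() < 2:
        raise InvalidInputError(
            "all participants are singletons: within-person variance undefined"
        )
    if method == "reml":
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, np.ones((n_total, 1)), groups=ids)
            res = model.fit(reml=True)
        return VarianceComponents(
            sigma2_between=float(np.asarray(res.cov_re)[0, 0]),
            sigma2_within=float(res.scale),
            n_persons=k,
            n_obs=n_total,
            method="reml",
        )
    if method != "anova":
        raise InvalidInputError(f"unknown method {method!r}")
    grand = y.mean()
    group_means = np.array([y[ids == g].mean() for g in groups])
    ssw = sum(((y[ids == g] - m) ** 2).sum() for g, m in zip(groups, group_means))
    ssb = (counts * (group_means - grand) ** 2).sum()
    msw = ssw / (n_total - k)
    msb = ssb / (k - 1)
    n0 = (n_total - (counts**2).sum() / n_total) / (k - 1)
    sigma2_between = max(0.0, (msb - msw) / n0)
    return VarianceComponents(
        sigma2_between=float(sigma2_between),
        sigma2_within=float(msw),
        n_persons=k,
        n_obs=n_total,
        method="anova",
    )


@dataclass
class ModelResult:
    """Fitted random-intercept model: fixed-effect table and variance parts.

    ``params`` has one row per fixed term with columns B, SE, t, df, p.
    ``factor_levels`` maps each categorical predictor to its levels (first
    level = reference, coefficient 0).
    """

    params: pd.DataFrame
    cov_fixed: pd.DataFrame
    factor_levels: dict[str, list[str]]
    group_var: float
    resid_var: float
    n_obs: int
    n_persons: int
    df_resid: int
    sr: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    dropped_terms: list[str] = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        return self.params.loc[name]

    @property
    def icc(self) -> float:
        total = self.group_var + self.resid_var
        return self.group_var / total if total > 0 else 0.0


def _is_categorical(s: pd.Series) -> bool:
    return (
        s.dtype == object
        or isinstance(s.dtype, pd.CategoricalDtype)
        or s.dtype == bool
    )


def _build_design(
    data: pd.DataFrame, terms: Sequence[str]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(data))}
    factor_levels: dict[str, list[str]] = {}
    for t in terms:
        s = data[t]
        if _is_categorical(s):
            levels = [str(v) for v in sorted(s.astype(str).unique())]
            factor_levels[t] = levels
            for lvl in levels[1:]:
                cols[f"{t}[{lvl}]"] = (s.astype(str) == lvl).astype(float).values
        else:
            cols[t] = s.astype(float).values
    X = pd.DataFrame(cols, index=data.index)
    return X, factor_levels


def _check_rank(X: pd.DataFrame) -> None:
    """Raise SingularDesignError naming columns that add no rank."""
    arr = X.values
    rank = np.linalg.matrix_rank(arr)
    if rank == X.shape[1]:
        return
    collinear = []
    kept: list[int] = []
    current = 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(arr[:, kept + [j]])
        if r > current:
            kept.append(j)
            current = r
        else:
            collinear.append(X.columns[j])
    raise SingularDesignError(collinear)


def fit_day_level_model(
    data: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    covariates: Sequence[str] = (),
    groups: str = "participant_id",
    compute_sr: bool = False,
) -> ModelResult:
    """Random-intercept model of a day-level outcome (REML).

    Categorical predictors are dummy-coded against their first (sorted) level;
    continuous ones enter as-is.  Inference uses the residual-df
    approximation ``df = n_obs - rank(X)`` with two-sided t tests.  With
    ``compute_sr`` a semipartial correlation is attached per focal predictor
    column (continuous terms only).
    """
    import statsmodels.api as sm

    terms = [*predictors, *covariates]
    work = data.dropna(subset=[outcome, groups, *terms]).reset_index(drop=True)
    if work.empty:
        raise InvalidInputError("no complete rows to fit")
    X, factor_levels = _build_design(work, terms)
    _check_rank(X)
    y = work[outcome].astype(float).values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=work[groups].values)
        res = model.fit(reml=True)
    k = X.shape[1]
    df_resid = len(work) - int(np.linalg.matrix_rank(X.values))
    b = pd.Series(res.fe_params, index=X.columns)
    se = pd.Series(np.asarray(res.bse_fe), index=X.columns)
    tval = b / se
    pval = 2.0 * stats.t.sf(np.abs(tval), df_resid)
    params = pd.DataFrame(
        {"B": b, "SE": se, "t": tval, "df": df_resid, "p": pval}
    )
    cov = pd.DataFrame(
        np.asarray(res.cov_params())[:k, :k], index=X.columns, columns=X.columns
    )
    result = ModelResult(
        params=params,
        cov_fixed=cov,
        factor_levels=factor_levels,
        group_var=float(np.asarray(res.cov_re)[0, 0]),
        resid_var=float(res.scale),
        n_obs=len(work),
        n_persons=int(work[groups].nunique()),
        df_resid=df_resid,
        converged=bool(res.converged),
    )
    if compute_sr:
        for p in predictors:
            if p in X.columns and p != "Intercept" and p not in factor_levels:
                others = [c for c in X.columns if c not in ("Intercept", p)]
                try:
                    result.sr[p] = semipartial_r(
                        work.assign(**{c: X[c] for c in X.columns if c != "Intercept"}),
                        outcome, p, others,
                    )
                except InvalidInputError:
                    pass
    return result


def within_between_association(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: Sequence[str] = (),
    groups: str = "participant_id",
) -> ModelResult:
    """Model a day-level outcome on the between- and within-person parts of a
    predictor.

    The predictor is person-mean centered: its person mean (between) and the
    daily deviation from that mean (within) enter as separate fixed effects,
    so typical level and daily fluctuation get separate coefficients.  A
    predictor constant within every person has no within variation; the
    within term is then dropped with a warning.
    """
    work = data.dropna(subset=[outcome, groups, predictor, *covariates]).reset_index(
        drop=True
    )
    if work.empty:
        raise InvalidInputError("no complete rows to fit")
    centered = person_mean_center(work[predictor], work[groups])
    work[f"{predictor}_between"] = centered.between_values.values
    work[f"{predictor}_within"] = centered.within_deviations.values
    terms = [f"{predictor}_between", f"{predictor}_within"]
    dropped = []
    if np.allclose(work[f"{predictor}_within"], 0.0):
        warnings.warn(
            f"{predictor} is constant within every person; "
            "dropping the within-person term",
            UserWarning,
            stacklevel=2,
        )
        terms = [f"{predictor}_between"]
        dropped = [f"{predictor}_within"]
    result = fit_day_level_model(work, outcome, terms, covariates, groups)
    result.dropped_terms = dropped
    return result


def contrast(
    result: ModelResult,
    factor: str,
    weights: Mapping[str, float],
) -> tuple[float, float, float, int, float]:
    """Linear contrast over the levels of one categorical term.

    ``weights`` maps level labels to contrast weights summing to zero.  The
    reference level's coefficient is identically zero; the SE propagates
    through the fixed-effect covariance.  Returns (estimate, SE, t, df, p).
    """
    if factor not in result.factor_levels:
        raise InvalidInputError(f"{factor!r} is not a categorical term of this model")
    levels = result.factor_levels[factor]
    unknown = set(weights) - set(levels)
    if unknown:
        raise InvalidInputError(f"unknown levels in weights: {sorted(unknown)}")
    w = np.array([weights.get(lvl, 0.0) for lvl in levels])
    if not np.any(w):
        raise InvalidInputError("contrast weights are all zero")
    if abs(w.sum()) > 1e-12:
        raise InvalidInputError(
            f"contrast weights must sum to zero, got {w.sum():g}"
        )
    est = 0.0
    cvec = pd.Series(0.0, index=result.cov_fixed.columns)
    for lvl, wt in zip(levels, w):
        name = f"{factor}[{lvl}]"
        if name in result.params.index:  # reference level contributes 0
            est += wt * result.params.loc[name, "B"]
            cvec[name] = wt
    var = float(cvec.values @ result.cov_fixed.values @ cvec.values)
    se = math.sqrt(max(var, 0.0))
    df = result.df_resid
    tstat = est / se if se > 0 else math.nan
    p = 2.0 * stats.t.sf(abs(tstat), df) if se > 0 else math.nan
    return float(est), se, float(tstat), int(df), float(p)


def semipartial_r(
    data: pd.DataFrame,
    outcome: str,
    focal: str,
    others: Sequence[str] = (),
) -> float:
    """Semipartial correlation of the outcome with the focal predictor.

    Classic definition: residualize the focal predictor on the other terms
    (OLS with intercept) and correlate the outcome with that residual.  The
    caller supplies the focal variable on the centering level at which it
    enters the model (e.g. the within-person deviation for a within effect).
    """
    work = data.dropna(subset=[outcome, focal, *others])
    y = work[outcome].astype(float).values
    x = work[focal].astype(float).values
    if len(work) < 3:
        raise InvalidInputError("need >= 3 rows for a semipartial correlation")
    if others:
        Z = np.column_stack(
            [np.ones(len(work))] + [work[c].astype(float).values for c in others]
        )
        beta, *_ = np.linalg.lstsq(Z, x, rcond=None)
        resid = x - Z @ beta
    else:
        resid = x - x.mean()
    if np.std(resid) < 1e-12 * max(1.0, np.std(x)):
        raise InvalidInputError(
            "focal predictor has no variance left after residualizing "
            "on the other terms"
        )
    r = float(np.corrcoef(y, resid)[0, 1])
    return max(-1.0, min(1.0, r))
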