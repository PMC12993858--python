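"""Random-intercept linear mixed models and the condition-index OLS.

Sample-level models regress (z-scored) bioassessment metrics on z-scored
development densities and land cover with independent (crossed) random
intercepts for ecoregion and acid-mine-drainage presence; network-level
models regress (z-scored) topology metrics on the two development presence
flags with a watershed (HUC8) random intercept. Estimation is by restricted
maximum likelihood; confidence intervals and p-values use the Wald normal
approximation (beta +/- 1.96*se). Significance stars: * p<0.05, ** p<0.01,
*** p<0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import CollinearityError, ConfigurationError, ConvergenceError, InputError

RESULT_COLUMNS = ["term", "beta", "se", "ci_low", "ci_high", "p", "stars"]


def zscore(values) -> np.ndarray:
    """(x - mean) / sd with sample sd (ddof=1); errors on zero variance."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InputError("z-scoring requires at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise InputError("z-scoring is undefined for zero-variance input")
    return (x - x.mean()) / sd


def stars(p: float) -> str:
    if not 0.0 <= p <= 1.0:
        raise InputError(f"p-value {p!r} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class ModelSpec:
    """Declarative model description.

    ``fixed`` terms and the response are data columns; ``zscore_fixed``
    names the fixed terms to standardize before fitting. ``sample_filter``
    is an optional pandas query string (e.g. ``"season == 'spring'"``).
    """

    response: str
    fixed: list[str]
    random_intercepts: list[str]
    zscore_response: bool = True
    zscore_fixed: tuple[str, ...] = ()
    sample_filter: str | None = None


@dataclass
class ModelResult:
    terms: pd.DataFrame  # RESULT_COLUMNS
    n: int
    converged: bool
    group_variances: dict[str, float] = field(default_factory=dict)
    residual_variance: float = float("nan")
    method: str = "reml"


def _prepare(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    if spec.sample_filter:
        data = data.query(spec.sample_filter)
    needed = [spec.response] + list(spec.fixed) + list(spec.random_intercepts)
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise InputError(f"model data is missing column(s): {missing}")
    data = data.dropna(subset=needed).copy()
    if len(data) < len(spec.fixed) + 2:
        raise InputError("too few rows to fit the model")
    for term in spec.fixed:
        data[term] = data[term].astype(float)
    if spec.zscore_response:
        data[spec.response] = zscore(data[spec.response])
    for term in spec.zscore_fixed:
        data[term] = zscore(data[term])
    return data


def _wald_table(names, beta, se) -> pd.DataFrame:
    beta, se = np.asarray(beta, dtype=float), np.asarray(se, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(se > 0, 2.0 * stats.norm.sf(np.abs(beta) / se), np.nan)
    return pd.DataFrame(
        {
            "term": names,
            "beta": beta,
            "se": se,
            "ci_low": beta - 1.96 * se,
            "ci_high": beta + 1.96 * se,
            "p": p,
            "stars": ["" if np.isnan(v) else stars(v) for v in p],
        }
    )


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Fit the spec's linear mixed model by REML.

    Independent random intercepts are fit for each grouping factor
    (variance-component encoding over a single dummy group, so the factors
    are crossed). Grouping factors with fewer than two observed levels are
    dropped with a warning; with no factors left the fit degenerates to
    ordinary least squares, which matches the mixed fit exactly in that
    case. Non-convergence raises :class:`ConvergenceError` with diagnostics.
    """
    data = _prepare(data, spec)
    factors = []
    for g in spec.random_intercepts:
        if data[g].nunique() >= 2:
            factors.append(g)
        else:
            warnings.warn(
                f"random intercept {g!r} has a single level and was dropped",
                stacklevel=2,
            )

    exog = sm.add_constant(data[list(spec.fixed)], has_constant="add")
    endog = data[spec.response].to_numpy(dtype=float)
    names = ["const"] + list(spec.fixed)

    if not factors:
        ols = sm.OLS(endog, exog).fit()
        table = _wald_table(names, ols.params.to_numpy(), ols.bse.to_numpy())
        return ModelResult(
            terms=table,
            n=len(data),
            converged=True,
            residual_variance=float(ols.scale),
            method="ols",
        )

    # patsy-safe internal names: response _y, fixed _x<i>, factors _g<i>.
    # The first factor supplies MixedLM's grouping structure; any further
    # factors enter as variance components, giving crossed intercepts.
    safe = pd.DataFrame({"_y": endog})
    for i, term in enumerate(spec.fixed):
        safe[f"_x{i}"] = data[term].to_numpy(dtype=float)
    for i, g in enumerate(factors):
        safe[f"_g{i}"] = data[g].astype(str).to_numpy()
    formula = "_y ~ " + (" + ".join(f"_x{i}" for i in range(len(spec.fixed))) or "1")
    vc_formula = {f"_g{i}": f"0 + C(_g{i})" for i in range(1, len(factors))}
    diagnostics = {"n": len(data), "response": spec.response, "random_intercepts": factors}
    model = smf.mixedlm(
        formula, safe, groups=safe["_g0"], re_formula="1",
        vc_formula=vc_formula or None,
    )
    result, fallback, last_error = None, None, None
    for method in ("powell", "bfgs", "lbfgs"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                candidate = model.fit(reml=True, method=method)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_error = exc
            continue
        if candidate.converged:
            result = candidate
            break
        fallback = fallback or candidate
    if result is None and fallback is not None:
        # boundary fits (variance ~ 0) routinely trip the flag; keep the
        # estimate but signal it
        warnings.warn(
            f"mixed model for {spec.response!r} did not report convergence; "
            f"estimates retained ({diagnostics})",
            stacklevel=2,
        )
        result = fallback
    if result is None:
        raise ConvergenceError(
            f"mixed model fit failed{f': {last_error}' if last_error else ''}",
            diagnostics=diagnostics,
        )
    table = _wald_table(names, result.fe_params.to_numpy(), result.bse_fe.to_numpy())
    group_var = {factors[0]: float(result.cov_re.iloc[0, 0])}
    for name, value in zip(sorted(vc_formula), np.atleast_1d(result.vcomp)):
        group_var[factors[int(name[2:])]] = float(value)
    return ModelResult(
        terms=table,
        n=len(data),
        converged=bool(result.converged),
        group_variances=group_var,
        residual_variance=float(result.scale),
    )


def fit_ols_r2(
    ensemble: pd.DataFrame,
    predictors: tuple[str, ...] = ("size", "connectance", "modularity", "mean_strength"),
    response: str = "ibi",
) -> tuple[float, pd.Series]:
    """Ordinary least squares of the network condition index on topology
    metrics; returns (R^2, coefficients). Collinear predictors are
    signalled."""
    missing = [c for c in (*predictors, response) if c not in ensemble.columns]
    if missing:
        raise InputError(f"ensemble table is missing column(s): {missing}")
    data = ensemble.dropna(subset=[*predictors, response])
    X = sm.add_constant(data[list(predictors)].astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise CollinearityError("predictors are collinear (rank-deficient design)")
    fit = sm.OLS(data[response].astype(float), X).fit()
    return float(fit.rsquared), fit.params


def results_table(fits: dict[str, ModelResult]) -> pd.DataFrame:
    """Stack per-response term tables into one long results frame."""
    frames = []
    for response, result in fits.items():
        t = result.terms.copy()
        t.insert(0, "response", response)
        t["n"] = result.n
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
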