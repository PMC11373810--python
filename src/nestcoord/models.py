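"""Stage-trend and cross-stage models of parental coordination.

Three fits mirror the study's inferential layer:

* incubation trend — Gamma GLMM with an inverse link: opposite-activity
  seconds ~ incubation phase (days before hatching, continuous) x year,
  with a pair random intercept.  No installed Python library fits a Gamma
  GLMM, so the marginal likelihood is maximized here directly, integrating
  the single random intercept by Gauss-Hermite quadrature;
* chick-rearing trend — Gaussian LMM (statsmodels MixedLM): coordination
  index ~ phase (early/mid) x year + pair random intercept, with Tukey-
  adjusted pairwise contrasts of all phase x year cell means;
* cross-stage link — one ordinary linear model per chick-rearing phase:
  chick coordination index ~ early + mid + late incubation coordination,
  with variance-inflation factors and a pair-resampling bootstrap
  (percentile intervals; two-sided p as twice the zero-crossing fraction).

Fixed-effect significance is reported as type-III Wald chi-square tests:
each term's coefficient block tested against zero in the presence of every
other term, with sum-to-zero coding for the categorical factors so the
tests are invariant to the reference level.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, special, stats

import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools.numdiff import approx_hess

from .core import ValidationError


class ConvergenceError(RuntimeError):
    """An optimizer failed to converge; never reported silently."""


@dataclass
class ModelReport:
    """Fitted terms with estimates, SEs, type-III Wald tests, and metadata."""

    name: str
    family: str
    link: str
    random_effects: str
    terms: pd.DataFrame  # term, df, estimate, se, stat, stat_value, p_value
    n_obs: int
    n_groups: Optional[int] = None
    extras: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"Model: {self.name}",
            f"Family(link): {self.family}({self.link}); random: {self.random_effects}",
            f"N = {self.n_obs}"
            + (f" observations, {self.n_groups} pairs" if self.n_groups else ""),
            self.terms.to_string(index=False),
        ]
        for key, val in self.extras.items():
            if isinstance(val, pd.DataFrame):
                lines.append(f"\n{key}:\n{val.to_string(index=False)}")
            else:
                lines.append(f"{key}: {val}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "name": self.name,
            "family": self.family,
            "link": self.link,
            "random_effects": self.random_effects,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "terms": self.terms.to_dict(orient="records"),
        }
        for key, val in self.extras.items():
            out[key] = (
                val.to_dict(orient="records") if isinstance(val, pd.DataFrame) else val
            )
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), default=float, **kwargs)

    def term(self, name: str) -> pd.Series:
        match = self.terms[self.terms["term"] == name]
        if match.empty:
            raise KeyError(f"no term {name!r}; have {list(self.terms['term'])}")
        return match.iloc[0]


def wald_type3(
    params: np.ndarray, cov: np.ndarray, design_info
) -> pd.DataFrame:
    """Type-III Wald chi-square per model term: b' V^-1 b on each block."""
    rows = []
    for term, sl in design_info.term_name_slices.items():
        b = np.asarray(params[sl], dtype=float)
        V = np.asarray(cov)[sl, sl]
        stat = float(b @ np.linalg.solve(V, b))
        df = len(b)
        se = float(np.sqrt(np.diag(V))[0]) if df == 1 else float("nan")
        rows.append(
            {
                "term": term,
                "df": df,
                "estimate": float(b[0]) if df == 1 else float("nan"),
                "se": se,
                "stat": "Chisq",
                "stat_value": stat,
                "p_value": float(stats.chi2.sf(stat, df)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gamma GLMM with inverse link (single random intercept)
# ---------------------------------------------------------------------------


@dataclass
class GammaGLMMResult:
    params: np.ndarray  # fixed effects, original response scale
    cov_params: np.ndarray
    sigma_group: float  # random-intercept SD on the linear-predictor scale
    shape: float  # Gamma shape parameter
    llf: float
    n_obs: int
    n_groups: int
    exog_names: list

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))


def fit_gamma_glmm(
    endog: np.ndarray,
    exog: np.ndarray,
    groups: np.ndarray,
    exog_names: Optional[Sequence[str]] = None,
    n_quad: int = 40,
) -> GammaGLMMResult:
    """Maximum-likelihood Gamma GLMM, inverse link, one random intercept.

    The group random effect is integrated out with ``n_quad``-node
    Gauss-Hermite quadrature; the likelihood is maximized over
    (fixed effects, log random-SD, log shape) with L-BFGS-B and the
    covariance taken from the numerical Hessian at the optimum.  The
    response is internally rescaled to unit mean for numerical balance
    (the inverse link makes coefficients scale as 1/response).
    """
    y = np.asarray(endog, dtype=float)
    X = np.asarray(exog, dtype=float)
    if np.any(y <= 0):
        raise ValidationError("Gamma response must be strictly positive")
    n, p = X.shape
    codes, _ = pd.factorize(np.asarray(groups))
    n_groups = int(codes.max()) + 1
    order = np.argsort(codes, kind="stable")
    y, X, codes = y[order], X[order], codes[order]
    counts = np.bincount(codes, minlength=n_groups)
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))

    scale = float(y.mean())
    ys = y / scale

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    logw = np.log(weights) - 0.5 * np.log(np.pi)
    sq2 = np.sqrt(2.0)
    log_ys = np.log(ys)

    def nll(theta: np.ndarray) -> float:
        beta = theta[:p]
        sig = np.exp(theta[p])
        k = np.exp(theta[p + 1])
        eta = X @ beta
        etaq = eta[:, None] + sq2 * sig * nodes[None, :]
        ok = etaq > 0
        safe = np.where(ok, etaq, 1.0)
        logf = (
            k * np.log(k)
            - special.gammaln(k)
            + (k - 1.0) * log_ys[:, None]
            - k * ys[:, None] * safe
            + k * np.log(safe)
        )
        logf = np.where(ok, logf, -np.inf)
        per = np.add.reduceat(logf, starts, axis=0)  # (n_groups, n_quad)
        ll = special.logsumexp(per + logw[None, :], axis=1)
        if not np.all(np.isfinite(ll)):
            return 1e10
        return -float(ll.sum())

    # starting values from the marginal Gamma GLM
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(ys, X, family=sm.families.Gamma(sm.families.links.InversePower()))
        glm_res = glm.fit()
    x0 = np.concatenate(
        [glm_res.params, [np.log(0.1), np.log(max(1.0 / glm_res.scale, 1e-2))]]
    )

    bounds = [(None, None)] * p + [(-12.0, 5.0), (-3.0, 8.0)]
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": 500}
    )
    if not res.success:
        res2 = optimize.minimize(
            nll, res.x, method="Nelder-Mead", options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-10}
        )
        if res2.fun <= res.fun:
            res = res2
    if not np.isfinite(res.fun) or res.fun >= 1e10:
        raise ConvergenceError("Gamma GLMM likelihood maximization failed")

    H = approx_hess(res.x, nll)
    cov_beta_s = None
    try:
        cov_all = np.linalg.inv(H)
        if np.all(np.diag(cov_all)[:p] > 0):
            cov_beta_s = cov_all[:p, :p]
    except np.linalg.LinAlgError:
        pass
    if cov_beta_s is None:
        # variance parameters at/near the boundary flatten the joint Hessian;
        # condition on them and use the fixed-effect information block
        warnings.warn(
            "variance parameters near the boundary: coefficient covariance "
            "conditioned on the random-effect variance",
            RuntimeWarning,
            stacklevel=2,
        )
        try:
            cov_beta_s = np.linalg.inv(H[:p, :p])
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular Hessian at the optimum: {exc}") from None
    if np.any(np.diag(cov_beta_s) <= 0):
        raise ConvergenceError("non-positive coefficient variance at the optimum")

    beta = res.x[:p] / scale
    cov_beta = cov_beta_s / scale**2
    return GammaGLMMResult(
        params=beta,
        cov_params=cov_beta,
        sigma_group=float(np.exp(res.x[p]) / scale),
        shape=float(np.exp(res.x[p + 1])),
        llf=-float(res.fun) - len(y) * np.log(scale),  # Jacobian of y -> y/scale
        n_obs=n,
        n_groups=n_groups,
        exog_names=list(exog_names) if exog_names is not None else None,
    )


def fit_incubation_trend(
    table: pd.DataFrame,
    response: str = "coordination_s",
    phase: str = "phase",
    year: str = "year",
    group: str = "pair_id",
    n_quad: int = 40,
) -> ModelReport:
    """Incubation coordination trend: Gamma GLMM, inverse link, pair intercept.

    ``response`` is the crude opposite-activity overlap in seconds (the
    duration itself, not the randomization index).  The year factor and its
    interaction with phase are dropped with a warning when only one year is
    present (rank deficiency).
    """
    df = table.copy()
    try:
        df[phase] = pd.to_numeric(df[phase])  # days before hatching, continuous
    except (TypeError, ValueError):
        raise ValidationError(
            "incubation phase must be numeric days before hatching"
        ) from None
    if df[response].le(0).any():
        raise ValidationError(
            "incubation coordination must be positive seconds (Gamma support)"
        )
    if df[group].nunique() < 2:
        raise ValidationError("need at least 2 pairs to identify the random intercept")
    if df[phase].nunique() < 2:
        raise ValidationError("need at least 2 incubation phases to fit a trend")
    has_year = year in df.columns and df[year].nunique() > 1
    if not has_year:
        if year in df.columns:
            warnings.warn(
                "single-year data: year term and interaction dropped",
                UserWarning,
                stacklevel=2,
            )
        formula = f"{response} ~ {phase}"
    else:
        formula = f"{response} ~ {phase} * C({year}, Sum)"
    ymat, X = patsy.dmatrices(formula, df, return_type="dataframe")
    fit = fit_gamma_glmm(
        ymat.to_numpy().ravel(),
        X.to_numpy(),
        df[group].to_numpy(),
        exog_names=list(X.columns),
        n_quad=n_quad,
    )
    terms = wald_type3(fit.params, fit.cov_params, X.design_info)
    return ModelReport(
        name="incubation_trend",
        family="Gamma",
        link="inverse",
        random_effects=f"(1|{group})",
        terms=terms,
        n_obs=fit.n_obs,
        n_groups=fit.n_groups,
        extras={
            "sigma_pair": fit.sigma_group,
            "gamma_shape": fit.shape,
            "loglik": fit.llf,
        },
    )


# ---------------------------------------------------------------------------
# Chick-rearing trend: Gaussian LMM + Tukey contrasts
# ---------------------------------------------------------------------------


def _tukey_cell_contrasts(
    params: np.ndarray,
    cov: np.ndarray,
    design_info,
    cells: pd.DataFrame,
    df_resid: float,
) -> pd.DataFrame:
    """All pairwise contrasts of cell estimated marginal means, Tukey-adjusted.

    The adjusted p uses the studentized range with the full number of cells,
    so every pairwise comparison is controlled jointly (conservative by
    design).  ``df_resid`` is the large-sample residual df approximation
    (observations minus fixed-effect parameters).
    """
    (L,) = patsy.build_design_matrices([design_info], cells)
    L = np.asarray(L)
    emm = L @ params
    vcv = L @ cov @ L.T
    k = len(cells)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            d = emm[i] - emm[j]
            var = vcv[i, i] + vcv[j, j] - 2 * vcv[i, j]
            se = float(np.sqrt(var))
            t = d / se
            p = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df_resid))
            a = " ".join(str(v) for v in cells.iloc[i])
            b = " ".join(str(v) for v in cells.iloc[j])
            rows.append(
                {
                    "contrast": f"{a} - {b}",
                    "estimate": float(d),
                    "se": se,
                    "t": float(t),
                    "p_tukey": p,
                }
            )
    return pd.DataFrame(rows)


def fit_chickrearing_trend(
    table: pd.DataFrame,
    response: str = "chick_index",
    phase: str = "phase",
    year: str = "year",
    group: str = "pair_id",
) -> ModelReport:
    """Chick-rearing index trend: Gaussian LMM with Tukey cell contrasts.

    Falls back to an ordinary fixed-effects model (with a warning) when the
    random intercept is unidentifiable because only one pair is present.
    """
    df = table.copy()
    if df[phase].nunique() < 2:
        raise ValidationError("both chick-rearing phases (EARLY, MID) must be present")
    has_year = year in df.columns and df[year].nunique() > 1
    rhs = f"C({phase}, Sum)" + (f" * C({year}, Sum)" if has_year else "")
    if year in df.columns and not has_year:
        warnings.warn("single-year data: year term dropped", UserWarning, stacklevel=2)
    formula = f"{response} ~ {rhs}"

    single_pair = df[group].nunique() < 2
    if single_pair:
        warnings.warn(
            "only one pair: random intercept unidentifiable, "
            "falling back to a fixed-effects model",
            UserWarning,
            stacklevel=2,
        )
        res = sm.OLS.from_formula(formula, data=df).fit()
        params = res.params.to_numpy()
        cov = res.cov_params().to_numpy()
        design_info = res.model.data.design_info
        random_desc = "none (single pair)"
        n_groups = 1
    else:
        model = sm.MixedLM.from_formula(formula, groups=df[group], data=df)
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # boundary fits (pair variance -> 0) can trip one optimizer but
            # not another; try a few before declaring failure
            for method in ("bfgs", "lbfgs", "cg", "powell"):
                try:
                    cand = model.fit(reml=True, method=method)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if cand.converged:
                    res = cand
                    break
        if res is None:
            raise ConvergenceError("MixedLM did not converge")
        k_fe = model.k_fe
        params = res.fe_params.to_numpy()
        cov = res.cov_params().to_numpy()[:k_fe, :k_fe]
        design_info = model.data.design_info
        random_desc = f"(1|{group})"
        n_groups = df[group].nunique()

    terms = wald_type3(params, cov, design_info)

    # Tukey contrasts over the observed phase x year cells
    cell_cols = [phase] + ([year] if has_year else [])
    observed = df[cell_cols].drop_duplicates().sort_values(cell_cols).reset_index(drop=True)
    full = df[phase].nunique() * (df[year].nunique() if has_year else 1)
    if len(observed) < full:
        warnings.warn(
            "empty phase x year cell: its contrasts are omitted",
            UserWarning,
            stacklevel=2,
        )
    df_resid = max(len(df) - len(params), 1)
    contrasts = _tukey_cell_contrasts(params, cov, design_info, observed, df_resid)

    return ModelReport(
        name="chickrearing_trend",
        family="Gaussian",
        link="identity",
        random_effects=random_desc,
        terms=terms,
        n_obs=len(df),
        n_groups=n_groups,
        extras={"tukey": contrasts},
    )


# ---------------------------------------------------------------------------
# Cross-stage link: OLS + VIF + pair-resampling bootstrap
# ---------------------------------------------------------------------------


def _bootstrap_ols(
    X: np.ndarray, y: np.ndarray, B: int, rng: np.random.Generator
) -> np.ndarray:
    n = len(y)
    out = np.empty((B, X.shape[1]))
    for b in range(B):
        idx = rng.integers(0, n, n)
        out[b], *_ = np.linalg.lstsq(X[idx], y[idx], rcond=None)
    return out


def fit_stage_link(
    table: pd.DataFrame,
    responses: Sequence[str] = ("chick_index_early", "chick_index_mid"),
    predictors: Sequence[str] = ("early_inc", "mid_inc", "late_inc"),
    n_boot: int = 10_000,
    rng: Union[int, np.random.Generator, None] = None,
) -> dict:
    """Cross-stage linear models with collinearity check and bootstrap.

    One ordinary linear model per chick-rearing phase on the complete-case
    per-pair table; F tests per term, VIF per predictor, and a
    case-resampling bootstrap over pairs (percentile 95% intervals; p as
    twice the fraction of bootstrap estimates crossing zero, capped at 1).
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    preds = list(predictors)
    responses = [r for r in responses if r in table.columns]
    if not responses:
        raise ValidationError("no response column present")
    reports = {}
    for resp in responses:
        df = table[[resp, *preds]].dropna()
        n, p = len(df), len(preds) + 1
        if n <= p:
            raise ValidationError(
                f"{resp}: n={n} <= parameters={p}; refusing to fit"
            )
        formula = f"{resp} ~ " + " + ".join(preds)
        res = sm.OLS.from_formula(formula, data=df).fit()
        exog = res.model.exog
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vifs = {
                preds[j - 1]: float(variance_inflation_factor(exog, j))
                for j in range(1, exog.shape[1])
            }
        if any(not np.isfinite(v) or v > 1e8 for v in vifs.values()):
            raise ValidationError(
                f"{resp}: perfectly collinear predictors (VIF -> infinity): {vifs}"
            )
        # per-term F tests (each term is 1 df: F = t^2)
        rows = []
        for name in res.params.index:
            t = res.tvalues[name]
            rows.append(
                {
                    "term": name,
                    "df": 1,
                    "estimate": float(res.params[name]),
                    "se": float(res.bse[name]),
                    "stat": "F.value",
                    "stat_value": float(t**2),
                    "p_value": float(res.pvalues[name]),
                }
            )
        terms = pd.DataFrame(rows)

        boot = _bootstrap_ols(
            exog, res.model.endog, n_boot, gen
        )
        brows = []
        for j, name in enumerate(res.params.index):
            bj = boot[:, j]
            lo, hi = np.percentile(bj, [2.5, 97.5])
            p_boot = min(1.0, 2.0 * min(float(np.mean(bj <= 0)), float(np.mean(bj >= 0))))
            brows.append(
                {
                    "term": name,
                    "estimate": float(res.params[name]),
                    "boot_mean": float(bj.mean()),
                    "ci_lo": float(lo),
                    "ci_hi": float(hi),
                    "p_boot": p_boot,
                }
            )
        reports[resp] = ModelReport(
            name=f"stage_link[{resp}]",
            family="Gaussian",
            link="identity",
            random_effects="none",
            terms=terms,
            n_obs=n,
            extras={
                "vif": vifs,
                "bootstrap": pd.DataFrame(brows),
                "n_boot": n_boot,
            },
        )
    return reports
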