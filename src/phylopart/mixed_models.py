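"""Nested random-effects variance decomposition and single-predictor
mixed-model environment screens.

The variance decomposition fits a random-intercept model with one
variance component per nesting level (e.g. site -> species, or
phylum -> family -> genus -> species) plus a residual, by REML, and
reports each component as a fraction of their sum.  The environment
screens fit, per variable, a linear and a quadratic mixed model with a
species random intercept, choose by ML AIC, and report the marginal R^2
(variance explained by the fixed effects alone); a likelihood-ratio test
compares slopes between two groups (e.g. angiosperms vs gymnosperms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning


@dataclass
class NestingSpec:
    """Ordered grouping factors, outermost first (columns of the data)."""

    factors: list[str]
    label: str = ""

    def __post_init__(self):
        if not self.factors:
            raise ValueError("need at least one grouping factor")
        if not self.label:
            self.label = "/".join(self.factors)


@dataclass
class VarianceComponents:
    """REML variance components (response units squared) and fractions."""

    components: dict[str, float]   # level name -> variance, incl. 'residual'
    fractions: dict[str, float]
    method: str = "REML"
    loglik: float = np.nan
    warnings: list[str] = field(default_factory=list)


def _nested_labels(df: pd.DataFrame, factors: list[str]) -> list[pd.Series]:
    """Level labels: factor l's groups are the joint values of factors[:l+1],
    so inner factors are nested within outer ones regardless of coding."""
    out = []
    acc = None
    for f in factors:
        col = df[f].astype(str)
        acc = col if acc is None else acc + "/" + col
        out.append(acc.rename(f))
    return out


def _indicator(labels: pd.Series) -> np.ndarray:
    codes, _ = pd.factorize(labels)
    Z = np.zeros((len(labels), codes.max() + 1))
    Z[np.arange(len(labels)), codes] = 1.0
    return Z


class _RemlProblem:
    """REML criterion for y = mu + sum_l u_l + e via the Woodbury identity.

    V = s2*I + Z G Z' with Z the stacked level indicators and G diagonal
    per level; each evaluation costs one Cholesky of a q x q matrix
    (q = total number of groups across levels).
    """

    def __init__(self, y: np.ndarray, Z_list: list[np.ndarray]):
        self.y = y
        self.n = len(y)
        self.Z = np.hstack(Z_list)
        self.block_sizes = [Z.shape[1] for Z in Z_list]
        self.ZtZ = self.Z.T @ self.Z
        self.Zty = self.Z.T @ self.y
        self.Zt1 = self.Z.T @ np.ones(self.n)
        self.yty = float(self.y @ self.y)
        self.ysum = float(self.y.sum())

    def _g_diag(self, level_vars: np.ndarray) -> np.ndarray:
        return np.repeat(level_vars, self.block_sizes)

    def neg_reml(self, theta: np.ndarray) -> float:
        """-2 * restricted log-likelihood (up to a constant) at
        theta = log(residual var), log(level vars...).

        Parameters are clamped to [-30, 10] on the log scale: with a
        degenerate (zero) residual variance the likelihood is unbounded,
        and the clamp pins such components at a numerical zero.
        """
        theta = np.clip(theta, -30.0, 10.0)
        s2 = np.exp(theta[0])
        g = self._g_diag(np.exp(theta[1:]))
        q = len(g)
        M = self.ZtZ + np.diag(s2 / g)
        try:
            L = np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            return np.inf
        logdet_M = 2.0 * np.sum(np.log(np.diag(L)))
        logdet_V = (self.n - q) * np.log(s2) + np.sum(np.log(g)) + logdet_M

        def vinv_quad(a_t_z, a_dot_b, b_t_z):
            # a' V^-1 b given Z'a, a'b, Z'b
            w = np.linalg.solve(M, b_t_z)
            return (a_dot_b - a_t_z @ w) / s2

        ytVy = vinv_quad(self.Zty, self.yty, self.Zty)
        otVo = vinv_quad(self.Zt1, float(self.n), self.Zt1)
        ytVo = vinv_quad(self.Zty, self.ysum, self.Zt1)
        if not np.isfinite(otVo) or otVo <= 0:
            return np.inf
        quad = ytVy - ytVo**2 / otVo
        return logdet_V + np.log(otVo) + quad


def variance_decomposition(
    df: pd.DataFrame,
    nesting: NestingSpec,
    response: str = "log_sla",
) -> VarianceComponents:
    """REML variance decomposition over a nested grouping hierarchy.

    Returns one variance per nesting level plus the residual, and their
    fractions of the total.  A level whose groups are all singletons is
    confounded with the residual; its component is reported as estimated
    (numerically ~0) with a warning.
    """
    data = df.dropna(subset=[response] + nesting.factors)
    y = data[response].to_numpy(dtype=float)
    n = len(y)
    labels = _nested_labels(data, nesting.factors)
    for lab in labels:
        if lab.nunique() < 2:
            raise ValueError(f"grouping level '{lab.name}' has < 2 groups")
    if n <= len(nesting.factors) + 1:
        raise ValueError("more variance components than observations")

    notes = []
    innermost = labels[-1]
    if (innermost.value_counts() == 1).all():
        notes.append(
            f"level '{innermost.name}' has all-singleton groups; its "
            "variance is confounded with the residual and estimates ~0"
        )

    Z_list = [_indicator(lab) for lab in labels]
    prob = _RemlProblem(y, Z_list)

    var_y = float(np.var(y, ddof=1))
    k = len(Z_list) + 1
    theta0 = np.log(np.full(k, var_y / k))
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = minimize(
            prob.neg_reml,
            theta0,
            method="L-BFGS-B",
            bounds=[(-30.0, 10.0)] * k,
        )
        res = minimize(
            prob.neg_reml,
            res.x,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-9, "maxfev": 2000},
        )
    if np.isnan(res.fun) or res.fun == np.inf:
        raise RuntimeError(f"REML did not converge: {res}")
    v = np.exp(np.clip(res.x, -30.0, 10.0))
    comps = {"residual": float(v[0])}
    for lab, var in zip(labels, v[1:]):
        comps[lab.name] = float(var)
    total = sum(comps.values())
    fractions = {kk: vv / total for kk, vv in comps.items()}
    return VarianceComponents(
        components=comps,
        fractions=fractions,
        loglik=float(-0.5 * res.fun),
        warnings=notes,
    )


def anova_balanced_oneway(y: np.ndarray, groups: np.ndarray) -> dict[str, float]:
    """Method-of-moments (ANOVA) variance components for a balanced
    one-way design; the closed-form oracle REML must match there."""
    y = np.asarray(y, dtype=float)
    uniq, codes = np.unique(groups, return_inverse=True)
    g = len(uniq)
    r = len(y) // g
    grand = y.mean()
    means = np.array([y[codes == i].mean() for i in range(g)])
    msb = r * np.sum((means - grand) ** 2) / (g - 1)
    msw = sum(np.sum((y[codes == i] - means[i]) ** 2) for i in range(g)) / (
        g * (r - 1)
    )
    sg = max((msb - msw) / r, 0.0)
    return {"group": sg, "residual": msw}


@dataclass
class EnvScreenResult:
    """AIC-chosen linear-vs-quadratic mixed model for one variable."""

    variable: str
    degree: int
    aic: dict[int, float]
    coefficients: dict[str, float]
    marginal_r2: float
    center: float
    n: int
    warnings: list[str] = field(default_factory=list)


def _design(env: np.ndarray, degree: int, center: float) -> np.ndarray:
    c = env - center
    cols = [np.ones_like(c), c]
    if degree == 2:
        cols.append(c * c)
    return np.column_stack(cols)


def _fit_mixedlm(y, X, groups, reml):
    """Fit a random-intercept model, falling back across optimizers:
    a boundary solution can report a non-finite likelihood."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = MixedLM(y, X, groups=groups)
        last_exc = None
        for method in ("bfgs", "lbfgs", "powell", "cg"):
            try:
                fit = model.fit(reml=reml, method=method)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
                continue
            if np.isfinite(fit.llf):
                return fit
        if last_exc is not None:
            raise np.linalg.LinAlgError(str(last_exc))
        raise np.linalg.LinAlgError("no optimizer produced a finite fit")


def _ml_aic(fit, n_fixed: int) -> float:
    # fixed effects + random-intercept variance + residual variance
    return float(2 * (n_fixed + 2) - 2 * fit.llf)


def env_screen(
    df: pd.DataFrame,
    env_var: str,
    species_col: str = "species",
    response: str = "log_sla",
) -> EnvScreenResult:
    """Single-variable mixed-model screen with AIC degree choice.

    Predictors are centered before squaring.  Degree is chosen on ML
    fits (the candidates differ in fixed effects); coefficients come
    from a REML refit of the winner.  Marginal R^2 =
    var(fixed predictions) / (that + intercept variance + residual).
    """
    data = df.dropna(subset=[response, env_var, species_col])
    env = data[env_var].to_numpy(dtype=float)
    if len(np.unique(env)) < 3:
        raise ValueError(f"'{env_var}' has fewer than 3 distinct values")
    y = data[response].to_numpy(dtype=float)
    groups = data[species_col].to_numpy()
    center = float(env.mean())

    notes = []
    aics: dict[int, float] = {}
    fits = {}
    for degree in (1, 2):
        X = _design(env, degree, center)
        try:
            fit = _fit_mixedlm(y, X, groups, reml=False)
            aics[degree] = _ml_aic(fit, X.shape[1])
            fits[degree] = fit
        except np.linalg.LinAlgError:
            notes.append(f"degree-{degree} ML fit singular")
    if not aics:
        raise RuntimeError(f"no model could be fitted for '{env_var}'")
    if 2 not in aics:
        notes.append("quadratic fit failed; falling back to degree 1")
    degree = min(aics, key=lambda d: (aics[d], d))

    X = _design(env, degree, center)
    refit = _fit_mixedlm(y, X, groups, reml=True)
    beta = np.asarray(refit.fe_params)
    names = ["intercept", env_var] + ([f"{env_var}^2"] if degree == 2 else [])
    fixed_pred = X @ beta
    var_f = float(np.var(fixed_pred, ddof=1))
    var_u = float(np.asarray(refit.cov_re)[0, 0])
    var_e = float(refit.scale)
    return EnvScreenResult(
        variable=env_var,
        degree=degree,
        aic=aics,
        coefficients=dict(zip(names, map(float, beta))),
        marginal_r2=var_f / (var_f + var_u + var_e),
        center=center,
        n=len(y),
        warnings=notes,
    )


def group_interaction_test(
    df: pd.DataFrame,
    env_var: str,
    group_col: str,
    species_col: str = "species",
    response: str = "log_sla",
    degree: int | None = None,
    min_group: int = 10,
) -> float:
    """Likelihood-ratio p-value for a group x environment interaction.

    Compares ML mixed-model fits (species random intercept) with and
    without the interaction of a two-level group factor with the
    environment terms, at the AIC-chosen degree unless given.
    """
    data = df.dropna(subset=[response, env_var, group_col, species_col])
    levels = data[group_col].unique()
    if len(levels) != 2:
        raise ValueError(f"'{group_col}' must have exactly 2 levels, got {len(levels)}")
    counts = data[group_col].value_counts()
    if counts.min() < min_group:
        raise ValueError(
            f"group '{counts.idxmin()}' has fewer than {min_group} records"
        )
    if degree is None:
        degree = env_screen(data, env_var, species_col, response).degree

    env = data[env_var].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    groups = data[species_col].to_numpy()
    gind = (data[group_col] == levels[1]).to_numpy(dtype=float)
    center = float(env.mean())
    X0 = np.column_stack([_design(env, degree, center), gind])
    env_terms = X0[:, 1 : 1 + degree]
    X1 = np.column_stack([X0, env_terms * gind[:, None]])

    fit0 = _fit_mixedlm(y, X0, groups, reml=False)
    fit1 = _fit_mixedlm(y, X1, groups, reml=False)
    lrt = max(2.0 * (fit1.llf - fit0.llf), 0.0)
    return float(chi2.sf(lrt, df=degree))
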