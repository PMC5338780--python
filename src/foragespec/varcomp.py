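"""Nested variance components and Gaussian random-intercept models.

The specialisation statistic is the proportion of total variance attributable
to the among-individual component of the two-level nested random-effects
model

    y_ijk = mu + a_i + b_ij + e_ijk,
    a_i ~ N(0, s2_ind),  b_ij ~ N(0, s2_trip),  e_ijk ~ N(0, s2_resid),

with trips j nested in individuals i.  Estimation is restricted maximum
likelihood (REML): the residual variance and fixed effects are profiled out
analytically and the variance ratios theta_k = s2_k / s2_resid are maximised
numerically under non-negativity bounds, so negative components are truncated
at zero by construction (flagged as boundary solutions).

The same profiled likelihood core drives the random-intercept covariate
models and the maximum-likelihood fits used for likelihood-ratio comparisons.
Residuals are homoscedastic throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .errors import (CollinearityError, InsufficientDataError,
                     NestingViolationError)

logger = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class VarianceDecomposition:
    """Variance, SD and percentage of total variance per hierarchical level."""

    levels: list[str]
    sigma2: np.ndarray
    flags: list[str] = field(default_factory=list)

    @property
    def sigma(self) -> np.ndarray:
        return np.sqrt(self.sigma2)

    @property
    def pct(self) -> np.ndarray:
        total = float(np.sum(self.sigma2))
        if total <= 0:
            return np.full(len(self.sigma2), np.nan)
        return 100.0 * self.sigma2 / total

    @property
    def individual_pct(self) -> float:
        """The specialisation estimate: % of variance at the individual level."""
        return float(self.pct[self.levels.index("individual")])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "level": self.levels,
            "sigma2": self.sigma2,
            "sigma": self.sigma,
            "pct": self.pct,
        })


@dataclass
class RandomInterceptFit:
    fixed_effects: dict[str, tuple[float, float]]
    sigma2_group: float
    sigma2_resid: float
    loglik_reml: float
    df_wald: int
    boundary: bool = False


def _indicator(labels) -> np.ndarray:
    codes, _ = pd.factorize(np.asarray(labels))
    Z = np.zeros((len(codes), codes.max() + 1))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def _make_blocks(y, X, factors):
    """Split (y, X) into blocks by the outer factor.

    ``factors[0]`` is the outer random factor (its indicator is all-ones
    within a block); later factors must be nested in it and are returned as
    local indicator matrices per block.  Block-diagonal covariance makes each
    likelihood evaluation O(sum of cubed block sizes) instead of O(n^3).
    """
    outer = pd.factorize(np.asarray(factors[0]))[0]
    blocks = []
    for g in range(outer.max() + 1):
        idx = np.flatnonzero(outer == g)
        m = len(idx)
        yX = np.column_stack([y[idx], X[idx]])
        # constant pieces of W: the all-ones outer block and inner Gram matrices
        grams = [np.ones((m, m))]
        for f in factors[1:]:
            Z = _indicator(np.asarray(f)[idx])
            grams.append(Z @ Z.T)
        blocks.append((yX, grams))
    return blocks


def _profiled_criterion(theta, blocks, n, p, reml):
    """-2 log (restricted) likelihood with sigma2_resid and beta profiled out.

    ``theta`` are variance ratios (component / residual); returns
    (criterion, beta, XtWiX_inv, sigma2_hat).
    """
    logdet_w = 0.0
    XtWiX = np.zeros((p, p))
    XtWiy = np.zeros(p)
    ytWiy = 0.0
    for yX, grams in blocks:
        m = len(yX)
        W = np.eye(m)
        for th, G in zip(theta, grams):
            if th > 0:
                W = W + th * G
        L = np.linalg.cholesky(W)
        logdet_w += 2.0 * float(np.sum(np.log(np.diag(L))))
        A = linalg.solve_triangular(L, yX, lower=True)
        ytWiy += float(A[:, 0] @ A[:, 0])
        XtWiy += A[:, 1:].T @ A[:, 0]
        XtWiX += A[:, 1:].T @ A[:, 1:]
    XtWiX_inv = linalg.inv(XtWiX)
    beta = XtWiX_inv @ XtWiy
    quad = max(ytWiy - float(beta @ XtWiy), 1e-300)
    if reml:
        dof = n - p
        s2 = quad / dof
        crit = dof * (math.log(s2) + _LOG2PI + 1.0) + logdet_w \
            + float(np.linalg.slogdet(XtWiX)[1])
    else:
        s2 = quad / n
        crit = n * (math.log(s2) + _LOG2PI + 1.0) + logdet_w
    return crit, beta, XtWiX_inv, s2


def _fit_lmm(y, X, factors, reml=True):
    """Maximise the profiled (RE)ML over non-negative variance ratios.

    ``factors`` are label arrays; the first is the outer blocking factor and
    any others must be nested in it.  Box-constrained quasi-Newton from a few
    starts followed by a Nelder-Mead polish; interior solutions are resolved
    to high precision so that REML matches closed-form nested-ANOVA
    estimators on balanced designs.  The zero bound truncates negative
    components.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    k = len(factors)
    blocks = _make_blocks(y, X, factors)

    def f(theta):
        return _profiled_criterion(np.clip(theta, 0.0, None), blocks, n, p, reml)[0]

    starts = [np.full(k, v) for v in (0.0, 1.0, 10.0)]
    if k == 2:
        starts += [np.array(v, float) for v in ((2.0, 0.0), (0.0, 2.0))]
    best = None
    for s0 in starts:
        res = optimize.minimize(f, s0, method="L-BFGS-B",
                                bounds=[(0.0, 1e8)] * k,
                                options={"ftol": 1e-12, "gtol": 1e-8,
                                         "maxiter": 200})
        if best is None or res.fun < best.fun:
            best = res
    polish = optimize.minimize(
        f, best.x, method="Nelder-Mead",
        bounds=[(0.0, 1e8)] * k,
        options={"xatol": 1e-9, "fatol": 1e-13, "maxiter": 2000})
    best_theta = np.clip(polish.x if polish.fun <= best.fun else best.x, 0.0, None)

    crit, beta, XtWiX_inv, s2 = _profiled_criterion(best_theta, blocks, n, p, reml)
    return {
        "theta": best_theta,
        "beta": beta,
        "beta_cov": s2 * XtWiX_inv,
        "sigma2_resid": s2,
        "sigma2_components": best_theta * s2,
        "loglik": -0.5 * crit,
        "boundary": bool((best_theta < 1e-9).any()),
    }


def loglik_ml(y, X, group_labels) -> float:
    """Maximised ML log-likelihood of a random-intercept model (for LR tests)."""
    return _fit_lmm(np.asarray(y, float), np.asarray(X, float),
                    [np.asarray(group_labels)], reml=False)["loglik"]


def _check_nesting(individual, trip) -> None:
    tab = pd.DataFrame({"ind": np.asarray(individual), "trip": np.asarray(trip)})
    per_trip = tab.groupby("trip")["ind"].nunique()
    if (per_trip > 1).any():
        bad = per_trip[per_trip > 1].index.tolist()
        raise NestingViolationError(f"trip labels {bad} appear under multiple individuals")


def fit_variance_components(y, individual, trip) -> VarianceDecomposition:
    """REML decomposition of variance into individual, trip-within-individual
    and residual levels.

    The individual percentage of total variance is the specialisation
    estimate.  Negative components are truncated at zero (bounded
    optimisation) and flagged.  Degenerate layouts are resolved without
    optimisation: a constant response yields an all-zero decomposition; an
    exactly-zero residual variance is handled by a method-of-moments pass on
    the trip means; one trip per individual makes the trip level
    unidentifiable, so it is dropped (variance attributed to individuals).
    """
    y = np.asarray(y, float)
    individual = np.asarray(individual)
    trip = np.asarray(trip)
    if len(y) != len(individual) or len(y) != len(trip):
        raise InsufficientDataError("y, individual and trip must align")
    if len(np.unique(individual)) < 2:
        raise InsufficientDataError("need at least two individuals")
    _check_nesting(individual, trip)
    levels = ["individual", "trip", "residual"]

    if np.var(y) < 1e-24:
        logger.warning("constant response: degenerate decomposition")
        return VarianceDecomposition(levels, np.zeros(3), flags=["degenerate"])

    tab = pd.DataFrame({"y": y, "ind": individual, "trip": trip})
    within_trip_var = tab.groupby("trip")["y"].var(ddof=1)
    trips_per_ind = tab.groupby("ind")["trip"].nunique()
    obs_per_trip = tab.groupby("trip")["y"].size()

    if (obs_per_trip == 1).all() and (trips_per_ind > 1).any():
        # one observation per trip (trip-level response): the trip and
        # residual levels coincide; report the within-individual variance at
        # the trip level
        fit = _fit_lmm(y, np.ones((len(y), 1)), [individual], reml=True)
        sigma2 = np.array([fit["sigma2_components"][0], fit["sigma2_resid"], 0.0])
        flags = ["trip-equals-residual"] + (["boundary"] if fit["boundary"] else [])
        return VarianceDecomposition(levels, sigma2, flags=flags)

    if within_trip_var.fillna(0.0).max() < 1e-24:
        # zero residual variance: likelihood is singular, use moments on means
        means = tab.groupby(["ind", "trip"])["y"].mean().reset_index()
        if (trips_per_ind > 1).any():
            s2_trip = float(means.groupby("ind")["y"].var(ddof=1).dropna().mean())
            mean_b = float(trips_per_ind.mean())
            s2_ind = max(0.0, float(means.groupby("ind")["y"].mean().var(ddof=1))
                         - s2_trip / mean_b)
        else:
            s2_trip = 0.0
            s2_ind = float(means["y"].var(ddof=1))
        logger.warning("zero within-trip variance: singular fit, moment estimates used")
        return VarianceDecomposition(levels, np.array([s2_ind, s2_trip, 0.0]),
                                     flags=["singular"])

    X = np.ones((len(y), 1))
    if (trips_per_ind == 1).all():
        fit = _fit_lmm(y, X, [individual], reml=True)
        sigma2 = np.array([fit["sigma2_components"][0], 0.0, fit["sigma2_resid"]])
        flags = ["trip-level-unidentifiable"] + (["boundary"] if fit["boundary"] else [])
        return VarianceDecomposition(levels, sigma2, flags=flags)

    fit = _fit_lmm(y, X, [individual, trip], reml=True)
    sigma2 = np.array([fit["sigma2_components"][0], fit["sigma2_components"][1],
                       fit["sigma2_resid"]])
    flags = ["boundary"] if fit["boundary"] else []
    if fit["boundary"]:
        logger.info("variance component truncated at zero (REML boundary)")
    return VarianceDecomposition(levels, sigma2, flags=flags)


def fit_random_intercept(y, x, group) -> RandomInterceptFit:
    """REML fit of y = b0 + b1 x + a_group + e with Wald SEs for the slope.

    Wald degrees of freedom are the conservative between-group count minus
    the number of fixed effects.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if np.ptp(x) == 0:
        raise CollinearityError("covariate x is constant")
    groups = np.asarray(group)
    n_groups = len(np.unique(groups))
    if n_groups < 2:
        raise InsufficientDataError("need at least two groups")
    X = np.column_stack([np.ones_like(x), x])

    # exact linear relation: profiled likelihood is singular, return the OLS fit
    ols_beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(res[0]) if len(res) else float(np.sum((y - X @ ols_beta) ** 2))
    if rss < 1e-12 * max(1.0, float(y @ y)):
        return RandomInterceptFit(
            fixed_effects={"intercept": (float(ols_beta[0]), 0.0),
                           "slope": (float(ols_beta[1]), 0.0)},
            sigma2_group=0.0, sigma2_resid=0.0, loglik_reml=math.inf,
            df_wald=max(1, n_groups - 2), boundary=True)

    fit = _fit_lmm(y, X, [groups], reml=True)
    se = np.sqrt(np.diag(fit["beta_cov"]))
    return RandomInterceptFit(
        fixed_effects={"intercept": (float(fit["beta"][0]), float(se[0])),
                       "slope": (float(fit["beta"][1]), float(se[1]))},
        sigma2_group=float(fit["sigma2_components"][0]),
        sigma2_resid=float(fit["sigma2_resid"]),
        loglik_reml=fit["loglik"],
        df_wald=max(1, n_groups - 2),
        boundary=fit["boundary"])


def consistency_regression(y_late, y_early, pair) -> tuple[float, float, float]:
    """Slope of late-season on early-season values with a pair-level random
    intercept; (slope, SE, Pearson r).

    Falls back to ordinary least squares when every pair contributes a single
    observation (the random intercept is then confounded with the residual).
    """
    y_late = np.asarray(y_late, float)
    y_early = np.asarray(y_early, float)
    pair = np.asarray(pair)
    if len(y_late) < 3:
        raise InsufficientDataError("need at least three paired samples")
    r = float(stats.pearsonr(y_early, y_late)[0])
    counts = pd.Series(pair).value_counts()
    if (counts == 1).all():
        res = stats.linregress(y_early, y_late)
        return float(res.slope), float(res.stderr), r
    fit = fit_random_intercept(y_late, y_early, pair)
    slope, se = fit.fixed_effects["slope"]
    return slope, se, r
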