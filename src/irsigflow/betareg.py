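"""Beta regression of subset abundances with a permutation minP FWER threshold.

Each combinational subset abundance y in (0,1) is modeled as
``y ~ Beta(mu * phi, (1 - mu) * phi)`` with ``logit(mu) = b0 + b_hiv * hiv +
b_age * old`` and precision ``phi > 0``; coefficients are estimated by maximum
likelihood and tested with Wald statistics from the observed information.

Family-wise error over the eight subsets is controlled by a permutation minP
threshold: each subject's vector of subset abundances is permuted across the
subset labels (within-subject, preserving the subject's abundance
inter-dependency), the full set of per-subset regressions is refit on each
permuted dataset, the minimum p-value across subsets is recorded per model
term, and the significance threshold is the 5th percentile of those minima —
computed as the ceil(0.05 * n_perm)-th smallest value, i.e. the 5th smallest
at the default 100 permutations. A subset is significant for a term iff its
observed Wald p is strictly below that term's threshold.

The likelihood is maximized directly (log-precision parameterization, analytic
gradient, BFGS with a logit-scale least-squares start) so that the ~100 x 8
fits per permutation run stay fast.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import digamma, expit, gammaln, logit, polygamma
from scipy.stats import norm

logger = logging.getLogger(__name__)

TERMS = ("hiv", "age")


class BetaRegError(ValueError):
    pass


@dataclasses.dataclass
class BetaRegFit:
    """Maximum-likelihood beta regression fit (logit mean link)."""

    params: dict[str, float]  # intercept, hiv, age
    se: dict[str, float]
    z: dict[str, float]
    p: dict[str, float]
    phi: float
    loglik: float
    converged: bool
    boundary_adjusted: bool

    def __post_init__(self) -> None:
        if not self.phi > 0:
            raise BetaRegError("precision phi must be > 0")


@dataclasses.dataclass
class PermThreshold:
    """Permutation minP distribution and the derived per-term threshold."""

    term: str
    n_perm: int
    seed: int
    minp_distribution: np.ndarray
    threshold: float


def design_matrix(design: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + HIV indicator + older-age indicator."""
    hiv = design["hiv"].to_numpy(dtype=float)
    old = (design["age_group"] == "old").to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(design)), hiv, old])
    return X, ["intercept", "hiv", "age"]


def interior_transform(y: np.ndarray) -> np.ndarray:
    """Squeeze boundary values into (0,1): y' = (y*(n-1) + 0.5)/n."""
    n = len(y)
    return (y * (n - 1) + 0.5) / n


def _negloglik_and_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray):
    beta, logphi = theta[:-1], theta[-1]
    phi = math.exp(min(logphi, 30.0))
    eta = X @ beta
    mu = expit(eta)
    # clip to keep gammaln arguments positive under extreme iterates
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    a, b = mu * phi, (1.0 - mu) * phi
    ll = np.sum(gammaln(phi) - gammaln(a) - gammaln(b)
                + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y))
    ystar = np.log(y) - np.log1p(-y)
    mustar = digamma(a) - digamma(b)
    dmu = phi * (ystar - mustar) * mu * (1.0 - mu)
    gbeta = X.T @ dmu
    dphi = np.sum(digamma(phi) - mu * digamma(a) - (1.0 - mu) * digamma(b)
                  + mu * np.log(y) + (1.0 - mu) * np.log1p(-y))
    glogphi = dphi * phi
    grad = np.append(gbeta, glogphi)
    return -ll, -grad


def _fisher_info(theta: np.ndarray, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Expected information in (beta, log phi) coordinates."""
    beta, logphi = theta[:-1], theta[-1]
    phi = math.exp(min(logphi, 30.0))
    mu = np.clip(expit(X @ beta), 1e-12, 1 - 1e-12)
    a, b = mu * phi, (1.0 - mu) * phi
    tg_a, tg_b = polygamma(1, a), polygamma(1, b)
    m = mu * (1.0 - mu)
    w = phi ** 2 * m ** 2 * (tg_a + tg_b)
    k = X.shape[1] + 1
    info = np.empty((k, k))
    info[:-1, :-1] = X.T @ (w[:, None] * X)
    c = phi * m * (mu * tg_a - (1.0 - mu) * tg_b)  # d score_eta / d phi, expected
    info[:-1, -1] = info[-1, :-1] = phi * (X.T @ c)
    kpp = np.sum(mu ** 2 * tg_a + (1.0 - mu) ** 2 * tg_b - polygamma(1, phi))
    info[-1, -1] = phi ** 2 * kpp
    return info


def _fisher_scoring(theta0: np.ndarray, X: np.ndarray, y: np.ndarray,
                    tol: float = 1e-7, max_iter: int = 50):
    """Newton steps on the expected information with step halving."""
    theta = theta0.copy()
    nll, grad = _negloglik_and_grad(theta, X, y)
    for _ in range(max_iter):
        info = _fisher_info(theta, X, y)
        try:
            step = np.linalg.solve(info, -grad)
        except np.linalg.LinAlgError:
            return theta, nll, grad, False
        scale = 1.0
        for _half in range(30):
            cand = theta + scale * step
            nll_new, grad_new = _negloglik_and_grad(cand, X, y)
            if np.isfinite(nll_new) and nll_new <= nll + 1e-12:
                break
            scale *= 0.5
        else:
            return theta, nll, grad, False
        theta, nll, grad = cand, nll_new, grad_new
        if np.max(np.abs(grad)) < tol * max(1.0, abs(nll)):
            return theta, nll, grad, True
    return theta, nll, grad, np.max(np.abs(grad)) < 1e-3


def _start_values(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least squares on the logit scale plus a moment start for phi."""
    z = logit(np.clip(y, 1e-6, 1 - 1e-6))
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    mu = expit(np.clip(X @ beta, -30, 30))
    resid_var = float(np.var(y - mu, ddof=X.shape[1])) or 1e-6
    phi0 = float(np.clip(np.mean(mu * (1 - mu)) / resid_var - 1.0, 1.0, 1e4))
    return np.append(beta, math.log(phi0))


def _hessian_fd(theta: np.ndarray, X: np.ndarray, y: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central finite differences of the analytic gradient."""
    k = len(theta)
    H = np.empty((k, k))
    for j in range(k):
        step = eps * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += step
        tm[j] -= step
        _, gp = _negloglik_and_grad(tp, X, y)
        _, gm = _negloglik_and_grad(tm, X, y)
        H[:, j] = (gp - gm) / (2.0 * step)
    return 0.5 * (H + H.T)


def fit_beta_mle(
    y: np.ndarray,
    X: np.ndarray,
    names: Sequence[str],
) -> BetaRegFit:
    """Fit the beta regression by BFGS on (beta, log phi)."""
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise BetaRegError("abundances must lie in [0, 1]")
    boundary = bool(np.any((y == 0) | (y == 1)))
    if boundary:
        y = interior_transform(y)
        logger.debug("boundary abundances squeezed with the interior transform")

    starts = [_start_values(X, y)]
    starts.append(np.append(np.zeros(X.shape[1]), math.log(10.0)))
    theta = nll = None
    converged = False
    for theta0 in starts:
        theta, nll, grad, converged = _fisher_scoring(theta0, X, y)
        if converged:
            break
        # fall back to quasi-Newton from the same start
        res = optimize.minimize(
            _negloglik_and_grad, theta0, args=(X, y), jac=True, method="BFGS",
            options={"gtol": 1e-6, "maxiter": 200},
        )
        if res.success or np.linalg.norm(res.jac) < 1e-3:
            theta, nll, converged = res.x, res.fun, True
            break
    if not converged:
        raise BetaRegError(
            f"beta regression did not converge; last iterate {theta} (nll {nll})"
        )
    H = _hessian_fd(theta, X, y)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    se_all = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    params = {nm: float(theta[i]) for i, nm in enumerate(names)}
    se = {nm: float(se_all[i]) for i, nm in enumerate(names)}
    z = {nm: (params[nm] / se[nm] if se[nm] > 0 else np.inf) for nm in names}
    p = {nm: float(np.clip(2.0 * norm.sf(abs(z[nm])), np.finfo(float).tiny, 1.0)) for nm in names}
    return BetaRegFit(
        params=params, se=se, z=z, p=p,
        phi=float(math.exp(theta[-1])),
        loglik=float(-nll),
        converged=True,
        boundary_adjusted=boundary,
    )


def fit_beta_regression(y: Sequence[float], design: pd.DataFrame) -> BetaRegFit:
    """Beta regression of one subset abundance on HIV status and age group."""
    y = np.asarray(y, dtype=float)
    if len(y) < 4:
        raise BetaRegError("need at least 4 observations")
    if len(y) != len(design):
        raise BetaRegError("y must align with the design table")
    if design["hiv"].nunique() < 2 or design["age_group"].nunique() < 2:
        raise BetaRegError("both HIV and age levels must be represented")
    X, names = design_matrix(design)
    return fit_beta_mle(y, X, names)


def fit_all_subsets(
    abundances: pd.DataFrame, design: pd.DataFrame
) -> dict[str, BetaRegFit]:
    """One beta regression per abundance column, keyed by column name."""
    return {col: fit_beta_regression(abundances[col].to_numpy(), design)
            for col in abundances.columns}


def _pvalues_per_term(
    abund: np.ndarray, X: np.ndarray, names: list[str]
) -> dict[str, np.ndarray]:
    """Wald p-values per term for every subset column; non-convergence -> p=1."""
    out = {t: np.ones(abund.shape[1]) for t in TERMS}
    for j in range(abund.shape[1]):
        try:
            fit = fit_beta_mle(abund[:, j], X, names)
        except BetaRegError:
            logger.warning("permutation fit failed for subset %d; p set to 1", j)
            continue
        if not fit.converged:
            continue
        for t in TERMS:
            out[t][j] = fit.p[t]
    return out


def minp_thresholds(
    abundances: pd.DataFrame,
    design: pd.DataFrame,
    n_perm: int = 100,
    seed: int = 0,
    scheme: str = "within_subject",
) -> dict[str, PermThreshold]:
    """Permutation minP thresholds for the HIV and age terms.

    ``scheme="within_subject"`` (the primary reading) permutes each subject's
    vector of subset abundances across the subset labels, independently per
    subject, preserving each subject's abundance inter-dependency.
    ``scheme="across_subjects"`` instead resamples each subset column across
    subjects; it is exposed for comparison only.

    One permutation stream serves both terms in a run.
    """
    if n_perm < 20:
        raise BetaRegError("n_perm must be >= 20")
    if scheme not in ("within_subject", "across_subjects"):
        raise BetaRegError(f"unknown permutation scheme {scheme!r}")
    X, names = design_matrix(design)
    abund = abundances.to_numpy(dtype=float)
    # canonicalize each subject's vector before permuting: a uniform random
    # permutation of a sorted row has the same law as one of the raw row, and
    # it makes the realized threshold invariant to subset column order
    abund_sorted = np.sort(abund, axis=1)
    rng = np.random.default_rng(seed)
    minima = {t: np.empty(n_perm) for t in TERMS}
    for b in range(n_perm):
        if scheme == "within_subject":
            perm = rng.permuted(abund_sorted, axis=1)
        else:
            perm = np.column_stack(
                [abund[rng.permutation(len(abund)), j] for j in range(abund.shape[1])]
            )
        pvals = _pvalues_per_term(perm, X, names)
        for t in TERMS:
            minima[t][b] = pvals[t].min()
    out = {}
    k = math.ceil(0.05 * n_perm)  # 5th smallest at n_perm=100; no interpolation
    for t in TERMS:
        sorted_min = np.sort(minima[t])
        out[t] = PermThreshold(
            term=t, n_perm=n_perm, seed=seed,
            minp_distribution=minima[t],
            threshold=float(sorted_min[k - 1]),
        )
    return out


def minp_threshold(
    abundances: pd.DataFrame,
    design: pd.DataFrame,
    term: str,
    n_perm: int = 100,
    seed: int = 0,
    scheme: str = "within_subject",
) -> PermThreshold:
    if term not in TERMS:
        raise BetaRegError(f"unknown term {term!r}")
    return minp_thresholds(abundances, design, n_perm, seed, scheme)[term]


def apply_thresholds(
    fits: Mapping[str, BetaRegFit],
    thresholds: Mapping[str, PermThreshold],
) -> dict[str, list[str]]:
    """Subsets significant per term: observed Wald p strictly below threshold."""
    out: dict[str, list[str]] = {}
    for term, thr in thresholds.items():
        out[term] = [name for name, fit in fits.items() if fit.p[term] < thr.threshold]
    return out
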