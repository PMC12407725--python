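"""Location-scale empirical-Bayes harmonization: the numerical core.

The model for feature ``g`` of subject ``j`` at site ``i`` is

    Y_ijg = alpha_g + X_ij beta_g + gamma_ig + delta_ig eps_ijg,
    eps_ijg ~ N(0, sigma_g^2),

with additive site effects ``gamma_ig`` constrained by
``sum_i n_i gamma_ig = 0`` for identifiability.  Harmonization proceeds in
three steps: (1) standardize the data with least-squares estimates of
(alpha_g, beta_g, sigma_g); (2) estimate per-site location/scale effects on
the standardized residuals and shrink them with parametric empirical Bayes
(normal prior on gamma, inverse-gamma prior on delta^2, hyperpriors
estimated across features within each site by the method of moments);
(3) remove the shrunken effects and restore the covariate structure.

The functions here operate on plain numpy arrays; :mod:`combatpredict.model`
wraps them in Model/Results objects with name checking and serialization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import HarmonizationInput
from .exceptions import (
    DataValidationError,
    DegenerateFeatureError,
    DegeneratePosteriorError,
    DegeneratePriorError,
    RankDeficientDesignError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StandardizationModel",
    "SitePrior",
    "SiteEffectEstimates",
    "fit_standardization",
    "standardize",
    "mom_site_estimates",
    "estimate_priors",
    "eb_posterior",
    "adjust",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class StandardizationModel:
    """Per-feature grand mean, covariate coefficients and pooled scale.

    ``alpha[g]`` is the grand mean (n_i-weighted across sites, or the
    reference site's mean in reference mode), ``beta[:, g]`` the covariate
    coefficients, and ``sigma[g] > 0`` the pooled residual scale of the full
    site-inclusive least-squares model.
    """

    alpha: np.ndarray  # (G,)
    beta: np.ndarray  # (p, G)
    sigma: np.ndarray  # (G,)
    covariate_names: list[str]
    feature_names: list[str]
    mean_model_kind: str = "linear"

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        G = self.alpha.shape[0]
        if self.beta.shape != (len(self.covariate_names), G):
            raise DataValidationError("beta shape inconsistent with names")
        if self.sigma.shape != (G,) or not (self.sigma > 0).all():
            raise DegenerateFeatureError("sigma must be strictly positive per feature")
        if len(self.feature_names) != G:
            raise DataValidationError("feature_names length inconsistent")

    def mean(self, X: np.ndarray) -> np.ndarray:
        """Predicted mean surface alpha + X beta, shape (n, G)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.alpha[None, :] + X @ self.beta


@dataclass
class SitePrior:
    """Across-feature hyperprior of one site: gamma ~ N(gamma_bar, tau2),
    delta^2 ~ InvGamma(lam, theta)."""

    gamma_bar: float
    tau2: float
    lam: float
    theta: float


@dataclass
class SiteEffectEstimates:
    """Raw and empirical-Bayes site effects for one site."""

    site: str
    n: int
    gamma_hat: np.ndarray  # (G,) raw within-site mean of Z
    delta2_hat: np.ndarray  # (G,) raw within-site sample variance of Z
    gamma_star: np.ndarray  # (G,) EB posterior location
    delta_star: np.ndarray  # (G,) EB posterior scale, > 0
    prior: SitePrior | None = None
    eb_used: bool = True
    n_iter: int = 0
    converged: bool = True
    is_reference: bool = False

    def __post_init__(self) -> None:
        for name in ("gamma_hat", "delta2_hat", "gamma_star", "delta_star"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if (self.delta2_hat < 0).any():
            raise DataValidationError(f"site {self.site}: negative delta2_hat")
        if (self.delta_star <= 0).any():
            raise DataValidationError(f"site {self.site}: delta_star must be > 0")


# ---------------------------------------------------------------------------
# Step 1: standardization


def _site_dummies(sites: np.ndarray, labels: list[str]) -> np.ndarray:
    S = np.zeros((sites.shape[0], len(labels)))
    for i, lab in enumerate(labels):
        S[sites == lab, i] = 1.0
    return S


def _locate_rank_deficiency(
    S: np.ndarray, X: np.ndarray, covariate_names: list[str]
) -> str:
    """Name a covariate column confounded with the site indicators."""
    base_rank = np.linalg.matrix_rank(S)
    D = S
    for j, name in enumerate(covariate_names):
        D = np.column_stack([D, X[:, j]])
        if np.linalg.matrix_rank(D) == base_rank:
            return name
        base_rank += 1
    return "<unknown>"


def fit_standardization(
    inp: HarmonizationInput,
    reference_site: str | None = None,
) -> StandardizationModel:
    """Least-squares standardization constants (Step 1).

    Solves Y on [site indicators | X]; under the n_i-weighted zero-sum
    constraint on the additive site effects the grand mean is the
    n_i-weighted average of the site coefficients.  ``sigma^2`` is the mean
    squared residual of the full model with divisor N (the total subject
    count).  In reference mode, alpha is the reference site's coefficient
    and sigma^2 is estimated from the reference site's residuals only.

    Only (alpha, beta, sigma) are retained; site terms are recomputed from
    the standardized data by :func:`mom_site_estimates`.
    """
    labels = inp.site_labels()
    if reference_site is not None and reference_site not in labels:
        raise DataValidationError(f"reference site '{reference_site}' not in data")
    S = _site_dummies(inp.sites, labels)
    D = np.column_stack([S, inp.X])
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        bad = _locate_rank_deficiency(S, inp.X, inp.covariate_names)
        raise RankDeficientDesignError(
            f"design is rank deficient: covariate '{bad}' is confounded with "
            "the site indicators (or with other covariates)"
        )
    B, *_ = np.linalg.lstsq(D, inp.Y, rcond=None)
    K = len(labels)
    site_coefs = B[:K, :]  # (K, G): per-site intercepts
    beta = B[K:, :]  # (p, G)
    n_i = S.sum(axis=0)  # (K,)
    resid = inp.Y - D @ B
    if reference_site is None:
        alpha = (n_i / n_i.sum()) @ site_coefs
        sigma2 = np.mean(resid**2, axis=0)
    else:
        r = labels.index(reference_site)
        alpha = site_coefs[r, :].copy()
        mask = inp.sites == reference_site
        sigma2 = np.mean(resid[mask] ** 2, axis=0)
    # sigma2 of an exactly-fit feature is pure roundoff (~eps^2 * scale)
    scale = np.mean(inp.Y**2, axis=0)
    zero = np.flatnonzero(sigma2 <= 1e-20 * (scale + 1.0))
    if zero.size:
        names = [inp.feature_names[g] for g in zero]
        raise DegenerateFeatureError(
            f"zero residual variance for feature(s) {names}; cannot standardize"
        )
    return StandardizationModel(
        alpha=alpha,
        beta=beta,
        sigma=np.sqrt(sigma2),
        covariate_names=list(inp.covariate_names),
        feature_names=list(inp.feature_names),
    )


def standardize(
    Y: np.ndarray,
    X: np.ndarray,
    model: StandardizationModel,
    covariate_names: list[str] | None = None,
) -> np.ndarray:
    """Z = (Y - alpha - X beta) / sigma, elementwise."""
    Y = np.asarray(Y, dtype=float)
    if not np.isfinite(Y).all():
        raise DataValidationError("non-finite values in Y")
    if covariate_names is not None and list(covariate_names) != model.covariate_names:
        raise DataValidationError(
            f"covariate names {list(covariate_names)} do not match the model's "
            f"{model.covariate_names}"
        )
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.size == 0:
        X = np.empty((Y.shape[0], 0))
    if X.shape[1] != len(model.covariate_names):
        raise DataValidationError(
            f"X has {X.shape[1]} columns, model expects {len(model.covariate_names)}"
        )
    return (Y - model.mean(X)) / model.sigma[None, :]


# ---------------------------------------------------------------------------
# Step 2: site effects, hyperpriors, empirical Bayes


def mom_site_estimates(
    Z: np.ndarray, sites: np.ndarray
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Raw per-site location/scale effects on the standardized data.

    gamma_hat_ig = within-site mean of Z; delta2_hat_ig = within-site sample
    variance (divisor n_i - 1).  Requires n_i >= 2 everywhere.
    """
    Z = np.asarray(Z, dtype=float)
    sites = np.asarray(sites).astype(str)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for lab in sorted(set(sites.tolist())):
        block = Z[sites == lab]
        if block.shape[0] < 2:
            raise DataValidationError(
                f"site '{lab}' too small for variance estimation (n={block.shape[0]})"
            )
        out[lab] = (block.mean(axis=0), block.var(axis=0, ddof=1))
    return out


def estimate_priors(gamma_hat: np.ndarray, delta2_hat: np.ndarray) -> SitePrior:
    """Method-of-moments hyperpriors of one site, across features.

    gamma_bar and tau2 are the across-feature mean and sample variance of
    gamma_hat.  The InvGamma(lam, theta) prior on delta^2 is matched to the
    across-feature mean m and sample variance s2 of delta2_hat through its
    moments mean = theta/(lam-1), var = theta^2/((lam-1)^2 (lam-2)):

        lam = (m^2 + 2 s2) / s2,    theta = (m^3 + m s2) / s2.
    """
    gamma_hat = np.asarray(gamma_hat, dtype=float)
    delta2_hat = np.asarray(delta2_hat, dtype=float)
    if gamma_hat.size < 2:
        raise DataValidationError("at least 2 features required to estimate priors")
    if (delta2_hat < 0).any():
        raise DataValidationError("delta2_hat must be nonnegative")
    gamma_bar = float(gamma_hat.mean())
    tau2 = float(gamma_hat.var(ddof=1))
    m = float(delta2_hat.mean())
    s2 = float(delta2_hat.var(ddof=1))
    if s2 <= 0:
        raise DegeneratePriorError(
            "across-feature variance of delta2_hat is zero; the inverse-gamma "
            "hyperprior is not identified"
        )
    lam = (m**2 + 2.0 * s2) / s2
    theta = (m**3 + m * s2) / s2
    return SitePrior(gamma_bar=gamma_bar, tau2=tau2, lam=lam, theta=theta)


def eb_posterior(
    Z_i: np.ndarray,
    prior: SitePrior,
    gamma_hat: np.ndarray | None = None,
    delta2_hat: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Fixed point of the conditional posterior-mean updates for one site.

    Under gamma_g ~ N(gamma_bar, tau2) and delta_g^2 ~ InvGamma(lam, theta),
    iterate jointly over all features:

        gamma*_g  <- (n tau2 gamma_hat_g + delta*2_g gamma_bar)
                     / (n tau2 + delta*2_g)
        delta*2_g <- (theta + 0.5 sum_j (Z_jg - gamma*_g)^2)
                     / (n/2 + lam - 1)

    initialized at the method-of-moments estimates, until the maximum
    absolute relative change of both vectors drops below ``tol`` or
    ``max_iter`` is reached (then a warning is logged and the last iterate
    returned).

    Returns (gamma_star, delta_star, n_iter, converged); note delta_star is
    the scale (square root of the variance fixed point).
    """
    Z_i = np.atleast_2d(np.asarray(Z_i, dtype=float))
    n = Z_i.shape[0]
    if n / 2.0 + prior.lam - 1.0 <= 0:
        raise DegeneratePosteriorError(
            f"degenerate inverse-gamma posterior: n/2 + lambda - 1 = "
            f"{n / 2.0 + prior.lam - 1.0:g} <= 0"
        )
    if gamma_hat is None:
        gamma_hat = Z_i.mean(axis=0)
    if delta2_hat is None:
        delta2_hat = Z_i.var(axis=0, ddof=1)
    g = np.asarray(gamma_hat, dtype=float).copy()
    d2 = np.asarray(delta2_hat, dtype=float).copy()
    denom_d = n / 2.0 + prior.lam - 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g_new = (n * prior.tau2 * gamma_hat + d2 * prior.gamma_bar) / (
            n * prior.tau2 + d2
        )
        ss = ((Z_i - g_new[None, :]) ** 2).sum(axis=0)
        d2_new = (prior.theta + 0.5 * ss) / denom_d
        change = max(
            np.max(np.abs(g_new - g) / np.maximum(np.abs(g), 1e-12)),
            np.max(np.abs(d2_new - d2) / np.maximum(np.abs(d2), 1e-12)),
        )
        g, d2 = g_new, d2_new
        if change < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "EB fixed-point iteration did not converge in %d iterations", max_iter
        )
    return g, np.sqrt(d2), it, converged


# ---------------------------------------------------------------------------
# Step 3: adjustment


def adjust(
    Z: np.ndarray,
    gamma_star: np.ndarray,
    delta_star: np.ndarray,
    model: StandardizationModel,
    X: np.ndarray,
) -> np.ndarray:
    """Remove site effects and restore the covariate structure:

        Y_combat = (sigma / delta*) (Z - gamma*) + alpha + X beta.
    """
    delta_star = np.asarray(delta_star, dtype=float)
    if (delta_star <= 0).any():
        raise DataValidationError("delta_star must be strictly positive")
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.size == 0:
        X = np.empty((Z.shape[0], 0))
    scale = model.sigma[None, :] / delta_star[None, :]
    return scale * (Z - np.asarray(gamma_star)[None, :]) + model.mean(X)
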