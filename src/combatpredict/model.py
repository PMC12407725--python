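"""Model/Results interface for ComBat harmonization.

``CombatModel`` holds the data; ``CombatModel.fit()`` returns a
``CombatResults`` carrying the standardization constants, per-site raw and
empirical-Bayes site effects, the harmonized matrix, and everything needed
to harmonize a *new* site later without access to the training data
(``CombatResults.predict_new_site``).  Results serialize to JSON and
round-trip exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    SiteEffectEstimates,
    SitePrior,
    StandardizationModel,
    adjust,
    eb_posterior,
    estimate_priors,
    fit_standardization,
    mom_site_estimates,
    standardize,
)
from .data import HarmonizationInput
from .exceptions import DataValidationError, DegeneratePriorError, SchemaError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

__all__ = [
    "CombatConfig",
    "CombatModel",
    "CombatResults",
    "fit_combat",
    "predict_new_site",
    "save_fit",
    "load_fit",
]


@dataclass
class CombatConfig:
    """Fit configuration. ``parametric`` is fixed true: only the parametric
    (normal / inverse-gamma) empirical-Bayes flavor is implemented."""

    eb: bool = True
    reference_site: str | None = None
    min_site_n: int = 3
    tol: float = 1e-6
    max_iter: int = 500
    allow_flat_prior: bool = False
    parametric: bool = True


class CombatModel:
    """Location-scale site-effect model for a subjects x features matrix.

    Parameters
    ----------
    data : HarmonizationInput
        Observations, site labels and covariate design.

    Examples
    --------
    >>> model = CombatModel.from_dataframe(df, site_col="site",
    ...                                    covariates=["age", "sex"])
    >>> res = model.fit()
    >>> res.harmonized            # site-effect-free matrix
    >>> res.save("fit.json")
    """

    def __init__(self, data: HarmonizationInput):
        self.data = data

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        site_col: str,
        covariates: list[str] | tuple[str, ...] = (),
        features: list[str] | None = None,
    ) -> "CombatModel":
        return cls(HarmonizationInput.from_dataframe(df, site_col, covariates, features))

    def fit(
        self,
        eb: bool = True,
        reference_site: str | None = None,
        min_site_n: int = 3,
        tol: float = 1e-6,
        max_iter: int = 500,
        allow_flat_prior: bool = False,
    ) -> "CombatResults":
        """Fit the pooled model and harmonize the training data."""
        config = CombatConfig(
            eb=eb,
            reference_site=reference_site,
            min_site_n=min_site_n,
            tol=tol,
            max_iter=max_iter,
            allow_flat_prior=allow_flat_prior,
        )
        inp = self.data
        inp.validate_site_sizes(min_site_n)
        std = fit_standardization(inp, reference_site=reference_site)
        Z = standardize(inp.Y, inp.X, std)
        mom = mom_site_estimates(Z, inp.sites)
        site_effects: dict[str, SiteEffectEstimates] = {}
        for lab in sorted(mom):
            block = Z[inp.sites == lab]
            site_effects[lab] = _estimate_site(
                lab, block, *mom[lab], config, is_reference=(lab == reference_site)
            )
        Y_harm = np.empty_like(inp.Y)
        for lab, eff in site_effects.items():
            mask = inp.sites == lab
            Y_harm[mask] = adjust(
                Z[mask], eff.gamma_star, eff.delta_star, std, inp.X[mask]
            )
        return CombatResults(
            standardization=std,
            site_effects=site_effects,
            config=config,
            harmonized=Y_harm,
            n_obs=inp.n_subjects,
            model=self,
        )


def _estimate_site(
    label: str,
    Z_block: np.ndarray,
    gamma_hat: np.ndarray,
    delta2_hat: np.ndarray,
    config: CombatConfig,
    is_reference: bool = False,
) -> SiteEffectEstimates:
    """Hyperpriors + EB posterior (or raw estimates) for one site block."""
    n = Z_block.shape[0]
    if is_reference:
        # the reference site defines the target space: identity adjustment
        return SiteEffectEstimates(
            site=label,
            n=n,
            gamma_hat=gamma_hat,
            delta2_hat=delta2_hat,
            gamma_star=np.zeros_like(gamma_hat),
            delta_star=np.ones_like(gamma_hat),
            prior=None,
            eb_used=False,
            is_reference=True,
        )
    prior: SitePrior | None = None
    if config.eb:
        try:
            prior = estimate_priors(gamma_hat, delta2_hat)
        except DegeneratePriorError:
            if not config.allow_flat_prior:
                raise
            logger.warning(
                "site %s: flat delta2 prior; falling back to method-of-moments "
                "estimates (allow_flat_prior=True)",
                label,
            )
    if prior is not None:
        gamma_star, delta_star, n_iter, converged = eb_posterior(
            Z_block,
            prior,
            gamma_hat=gamma_hat,
            delta2_hat=delta2_hat,
            tol=config.tol,
            max_iter=config.max_iter,
        )
        logger.debug("site %s: EB converged=%s after %d iterations", label, converged, n_iter)
        return SiteEffectEstimates(
            site=label,
            n=n,
            gamma_hat=gamma_hat,
            delta2_hat=delta2_hat,
            gamma_star=gamma_star,
            delta_star=delta_star,
            prior=prior,
            eb_used=True,
            n_iter=n_iter,
            converged=converged,
        )
    # eb disabled (or flat-prior fallback): use the raw estimates
    if (delta2_hat <= 0).any():
        raise DataValidationError(
            f"site {label}: zero raw variance with EB disabled; cannot rescale"
        )
    return SiteEffectEstimates(
        site=label,
        n=n,
        gamma_hat=gamma_hat,
        delta2_hat=delta2_hat,
        gamma_star=gamma_hat.copy(),
        delta_star=np.sqrt(delta2_hat),
        prior=None,
        eb_used=False,
    )


class CombatResults:
    """Fitted harmonization model.

    Attributes
    ----------
    standardization : StandardizationModel
    site_effects : dict mapping site label -> SiteEffectEstimates
    config : CombatConfig
    harmonized : ndarray (n_subjects, n_features)
        The training data with site effects removed (row order preserved).
    """

    def __init__(
        self,
        standardization: StandardizationModel,
        site_effects: dict[str, SiteEffectEstimates],
        config: CombatConfig,
        harmonized: np.ndarray | None = None,
        n_obs: int | None = None,
        model: CombatModel | None = None,
    ):
        self.standardization = standardization
        self.site_effects = site_effects
        self.config = config
        self.harmonized = harmonized
        self.n_obs = (
            n_obs
            if n_obs is not None
            else sum(e.n for e in site_effects.values())
        )
        self.model = model
        self._validate()

    def _validate(self) -> None:
        if self.n_obs != sum(e.n for e in self.site_effects.values()):
            raise DataValidationError("site sizes do not sum to the fitted sample size")
        if self.config.reference_site is None and self.site_effects:
            resid = sum(e.n * e.gamma_hat for e in self.site_effects.values())
            if np.max(np.abs(resid)) > 1e-8:
                raise DataValidationError(
                    "identifiability constraint sum_i n_i gamma_hat_ig = 0 violated"
                )

    # -- convenience -----------------------------------------------------

    @property
    def feature_names(self) -> list[str]:
        return self.standardization.feature_names

    @property
    def covariate_names(self) -> list[str]:
        return self.standardization.covariate_names

    def harmonized_frame(self, site_col: str = "site") -> pd.DataFrame:
        if self.harmonized is None or self.model is None:
            raise DataValidationError("harmonized training data not attached")
        inp = self.model.data
        d = {site_col: inp.sites}
        for j, c in enumerate(inp.covariate_names):
            d[c] = inp.X[:, j]
        for g, f in enumerate(self.feature_names):
            d[f] = self.harmonized[:, g]
        return pd.DataFrame(d)

    def summary(self) -> str:
        """Human-readable per-site summary table."""
        lines = [
            f"ComBat harmonization fit (combatpredict {__version__})",
            f"  features: {len(self.feature_names)}   subjects: {self.n_obs}   "
            f"sites: {len(self.site_effects)}",
            f"  empirical Bayes: {self.config.eb}   "
            f"reference site: {self.config.reference_site}",
            "",
            f"{'site':>12} {'n':>4} {'gamma_bar':>10} {'tau2':>9} "
            f"{'lambda':>8} {'theta':>8} {'mean|g*|':>9} {'mean d*':>8} {'iters':>6}",
        ]
        for lab in sorted(self.site_effects):
            e = self.site_effects[lab]
            p = e.prior
            lines.append(
                f"{lab:>12} {e.n:>4} "
                f"{(f'{p.gamma_bar:10.4f}' if p else '         -')} "
                f"{(f'{p.tau2:9.4f}' if p else '        -')} "
                f"{(f'{p.lam:8.2f}' if p else '       -')} "
                f"{(f'{p.theta:8.2f}' if p else '       -')} "
                f"{np.mean(np.abs(e.gamma_star)):9.4f} "
                f"{np.mean(e.delta_star):8.4f} "
                f"{e.n_iter:>6}"
            )
        return "\n".join(lines)

    def plot_site_effects(self, ax=None):
        """Scatter raw vs shrunken additive site effects (one point per
        site/feature); the vertical pull toward each site's prior mean
        visualizes the empirical-Bayes shrinkage. Requires matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for lab, e in self.site_effects.items():
            ax.scatter(e.gamma_hat, e.gamma_star, s=8, alpha=0.5, label=lab)
        lim = ax.get_xlim()
        ax.plot(lim, lim, color="grey", lw=0.8, zorder=0)
        ax.set_xlabel(r"raw site effect $\hat\gamma_{ig}$")
        ax.set_ylabel(r"EB posterior $\hat\gamma^*_{ig}$")
        return ax

    # -- out-of-sample prediction ---------------------------------------

    def predict_new_site(
        self,
        Y_new: np.ndarray,
        X_new: np.ndarray,
        site_label: str = "new_site",
        feature_names: list[str] | None = None,
        covariate_names: list[str] | None = None,
        estimation_mask: np.ndarray | None = None,
    ) -> tuple[SiteEffectEstimates, np.ndarray]:
        """Harmonize one new site using only this stored fit.

        Standardizes the new data with the stored (alpha, beta, sigma),
        estimates the new site's location/scale effects by the method of
        moments, fits across-feature hyperpriors from the new site's own
        estimates, shrinks with empirical Bayes (if the fit used it), and
        removes the effects.  The original fit is never modified and no
        training data is needed.

        ``estimation_mask`` restricts site-effect *estimation* to a subject
        subset (e.g. healthy controls); the adjustment is applied to all
        rows.
        """
        Y_new = np.atleast_2d(np.asarray(Y_new, dtype=float))
        if feature_names is not None:
            missing = [f for f in self.feature_names if f not in feature_names]
            extra = [f for f in feature_names if f not in self.feature_names]
            if missing or extra:
                raise DataValidationError(
                    f"feature mismatch with fit: missing={missing}, extra={extra}"
                )
            order = [list(feature_names).index(f) for f in self.feature_names]
            Y_new = Y_new[:, order]
        elif Y_new.shape[1] != len(self.feature_names):
            raise DataValidationError(
                f"Y_new has {Y_new.shape[1]} features, fit has "
                f"{len(self.feature_names)}"
            )
        n_new = Y_new.shape[0]
        if n_new < self.config.min_site_n:
            raise DataValidationError(
                f"new site has {n_new} subjects; minimum is {self.config.min_site_n}"
            )
        Z = standardize(Y_new, X_new, self.standardization, covariate_names)
        if estimation_mask is None:
            Z_est = Z
        else:
            estimation_mask = np.asarray(estimation_mask, dtype=bool)
            if estimation_mask.shape[0] != n_new:
                raise DataValidationError("estimation_mask length mismatch")
            if estimation_mask.sum() < self.config.min_site_n:
                raise DataValidationError(
                    f"only {int(estimation_mask.sum())} subjects available for "
                    f"site-effect estimation; minimum is {self.config.min_site_n}"
                )
            Z_est = Z[estimation_mask]
        gamma_hat = Z_est.mean(axis=0)
        delta2_hat = Z_est.var(axis=0, ddof=1)
        effects = _estimate_site(
            site_label,
            Z_est,
            gamma_hat,
            delta2_hat,
            self.config,
            is_reference=(site_label == self.config.reference_site),
        )
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim == 1:
            X_new = X_new[:, None]
        if X_new.size == 0:
            X_new = np.empty((n_new, 0))
        Y_harm = adjust(
            Z, effects.gamma_star, effects.delta_star, self.standardization, X_new
        )
        return effects, Y_harm

    def predict_batches(
        self,
        df: pd.DataFrame,
        site_col: str,
    ) -> tuple[dict[str, SiteEffectEstimates], pd.DataFrame]:
        """Split a table on its site column and harmonize each site
        independently; returns effects per site and the harmonized table."""
        inp = HarmonizationInput.from_dataframe(
            df, site_col, self.covariate_names, self.feature_names
        )
        out = df.copy()
        effects: dict[str, SiteEffectEstimates] = {}
        for lab in inp.site_labels():
            mask = inp.sites == lab
            eff, Y_harm = self.predict_new_site(
                inp.Y[mask], inp.X[mask], site_label=lab
            )
            effects[lab] = eff
            out.loc[mask, self.feature_names] = Y_harm
        return effects, out

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        std = self.standardization
        return {
            "schema_version": SCHEMA_VERSION,
            "package_version": __version__,
            "config": asdict(self.config),
            "n_obs": self.n_obs,
            "standardization": {
                "alpha": std.alpha.tolist(),
                "beta": std.beta.tolist(),
                "sigma": std.sigma.tolist(),
                "covariate_names": std.covariate_names,
                "feature_names": std.feature_names,
                "mean_model_kind": std.mean_model_kind,
            },
            "site_effects": {
                lab: {
                    "n": e.n,
                    "gamma_hat": e.gamma_hat.tolist(),
                    "delta2_hat": e.delta2_hat.tolist(),
                    "gamma_star": e.gamma_star.tolist(),
                    "delta_star": e.delta_star.tolist(),
                    "prior": asdict(e.prior) if e.prior is not None else None,
                    "eb_used": e.eb_used,
                    "n_iter": e.n_iter,
                    "converged": e.converged,
                    "is_reference": e.is_reference,
                }
                for lab, e in self.site_effects.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CombatResults":
        if not isinstance(d, dict) or "schema_version" not in d:
            raise SchemaError("not a combatpredict fit object (no schema_version)")
        if d["schema_version"] != SCHEMA_VERSION:
            raise SchemaError(
                f"unsupported schema version {d['schema_version']} "
                f"(expected {SCHEMA_VERSION})"
            )
        try:
            sd = d["standardization"]
            std = StandardizationModel(
                alpha=np.array(sd["alpha"], dtype=float),
                beta=np.array(sd["beta"], dtype=float),
                sigma=np.array(sd["sigma"], dtype=float),
                covariate_names=list(sd["covariate_names"]),
                feature_names=list(sd["feature_names"]),
                mean_model_kind=sd.get("mean_model_kind", "linear"),
            )
            effects = {}
            for lab, e in d["site_effects"].items():
                prior = SitePrior(**e["prior"]) if e["prior"] is not None else None
                effects[lab] = SiteEffectEstimates(
                    site=lab,
                    n=int(e["n"]),
                    gamma_hat=np.array(e["gamma_hat"], dtype=float),
                    delta2_hat=np.array(e["delta2_hat"], dtype=float),
                    gamma_star=np.array(e["gamma_star"], dtype=float),
                    delta_star=np.array(e["delta_star"], dtype=float),
                    prior=prior,
                    eb_used=bool(e["eb_used"]),
                    n_iter=int(e.get("n_iter", 0)),
                    converged=bool(e.get("converged", True)),
                    is_reference=bool(e.get("is_reference", False)),
                )
            config = CombatConfig(**d["config"])
            n_obs = int(d["n_obs"])
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"malformed fit object: {exc}") from exc
        return cls(
            standardization=std, site_effects=effects, config=config, n_obs=n_obs
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "CombatResults":
        try:
            with open(path, encoding="utf-8") as fh:
                d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"cannot parse fit file {path}: {exc}") from exc
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# functional aliases


def fit_combat(
    inp: HarmonizationInput, config: CombatConfig | None = None
) -> tuple[CombatResults, np.ndarray]:
    """Fit the pooled model; returns (results, harmonized matrix)."""
    config = config or CombatConfig()
    res = CombatModel(inp).fit(
        eb=config.eb,
        reference_site=config.reference_site,
        min_site_n=config.min_site_n,
        tol=config.tol,
        max_iter=config.max_iter,
        allow_flat_prior=config.allow_flat_prior,
    )
    return res, res.harmonized


def predict_new_site(
    fit: CombatResults,
    Y_new: np.ndarray,
    X_new: np.ndarray,
    site_label: str = "new_site",
    **kwargs,
) -> tuple[SiteEffectEstimates, np.ndarray]:
    """Functional form of :meth:`CombatResults.predict_new_site`."""
    return fit.predict_new_site(Y_new, X_new, site_label=site_label, **kwargs)


def save_fit(fit: CombatResults, path) -> None:
    fit.save(path)


def load_fit(path) -> CombatResults:
    return CombatResults.load(path)
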