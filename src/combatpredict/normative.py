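"""Normative reference models and centile scoring.

A normative reference is, per feature, a linear model of the harmonized
measure on age and sex with a constant residual SD; an individual's centile
is the normal-CDF position of their value within the predicted
distribution:

    centile = Phi((y - mu_hat(age, sex)) / sd_resid).

:func:`score_new_cohort` harmonizes a test cohort site by site using a
stored fit — estimating each site's effects from its healthy controls only,
then adjusting every subject of the site — and scores both the harmonized
and the raw values against the same reference, the comparison that isolates
what test-set harmonization contributes.

:func:`cohort_comparison` quantifies residual reference-vs-test
heterogeneity per feature with a two-sided Wilcoxon rank-sum test and the
rank-biserial correlation RBC = (wins - losses) / (n1 * n2), positive when
the test group tends higher.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataValidationError, HarmonizationError
from .model import CombatResults

logger = logging.getLogger(__name__)

__all__ = [
    "NormativeModel",
    "NormativeResults",
    "CentileTable",
    "fit_normative",
    "centile_scores",
    "score_new_cohort",
    "cohort_comparison",
]

_EPS = 1e-12


class NormativeModel:
    """Per-feature linear reference model of a harmonized cohort.

    Parameters
    ----------
    Y : ndarray (n, G)
        Harmonized measures of the reference cohort.
    X : ndarray (n, p)
        Covariates; must contain age and sex (by the given names).
    """

    def __init__(
        self,
        Y: np.ndarray,
        X: np.ndarray,
        feature_names: list[str] | None = None,
        covariate_names: list[str] = ("age", "sex"),
    ):
        self.Y = np.atleast_2d(np.asarray(Y, dtype=float))
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] != self.Y.shape[0]:
            raise DataValidationError("Y and X row counts differ")
        self.covariate_names = list(covariate_names)
        if self.X.shape[1] != len(self.covariate_names):
            raise DataValidationError("X columns do not match covariate_names")
        self.feature_names = (
            list(feature_names)
            if feature_names is not None
            else [f"feature_{g}" for g in range(self.Y.shape[1])]
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        features: list[str],
        covariates: list[str] = ("age", "sex"),
    ) -> "NormativeModel":
        return cls(
            df[list(features)].to_numpy(dtype=float),
            df[list(covariates)].to_numpy(dtype=float),
            feature_names=list(features),
            covariate_names=list(covariates),
        )

    def fit(self) -> "NormativeResults":
        """Least squares per feature; residual SD with divisor n - p - 1."""
        n, G = self.Y.shape
        p = self.X.shape[1]
        dof = n - (p + 1)
        if dof < 1:
            raise DataValidationError(
                f"reference cohort too small: n={n} leaves no residual degrees "
                f"of freedom for {p + 1} coefficients"
            )
        D = np.column_stack([np.ones(n), self.X])
        B, *_ = np.linalg.lstsq(D, self.Y, rcond=None)
        resid = self.Y - D @ B
        sd = np.sqrt((resid**2).sum(axis=0) / dof)
        zero = np.flatnonzero(sd <= _EPS)
        if zero.size:
            names = [self.feature_names[g] for g in zero]
            raise DataValidationError(
                f"degenerate reference: zero residual SD for feature(s) {names}"
            )
        return NormativeResults(
            coef=B,
            resid_sd=sd,
            feature_names=self.feature_names,
            covariate_names=self.covariate_names,
            n_obs=n,
        )


@dataclass
class NormativeResults:
    """Fitted normative reference: per-feature (intercept, age, sex)
    coefficients and residual SD."""

    coef: np.ndarray  # (p + 1, G), row 0 = intercept
    resid_sd: np.ndarray  # (G,)
    feature_names: list[str]
    covariate_names: list[str]
    n_obs: int
    combat_fit_tag: str | None = None  # provenance of the harmonization fit

    def predict_mean(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack([np.ones(len(X)), X]) @ self.coef

    def centile_scores(self, Y: np.ndarray, X: np.ndarray) -> np.ndarray:
        """Phi((y - mu_hat) / sd_resid) per cell, strictly inside (0, 1)."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not (np.isfinite(Y).all() and np.isfinite(X).all()):
            raise DataValidationError("non-finite values in Y or X")
        z = (Y - self.predict_mean(X)) / self.resid_sd[None, :]
        return np.clip(stats.norm.cdf(z), _EPS, 1.0 - _EPS)

    def summary(self) -> str:
        lines = [
            f"Normative reference ({self.n_obs} subjects, "
            f"{len(self.feature_names)} features)",
            f"{'feature':>12} {'intercept':>10} "
            + " ".join(f"{c:>9}" for c in self.covariate_names)
            + f" {'resid_sd':>9}",
        ]
        for g, f in enumerate(self.feature_names):
            coefs = " ".join(f"{self.coef[j + 1, g]:9.4f}" for j in range(len(self.covariate_names)))
            lines.append(
                f"{f:>12} {self.coef[0, g]:10.4f} {coefs} {self.resid_sd[g]:9.4f}"
            )
        return "\n".join(lines)


def fit_normative(
    Y: np.ndarray,
    X: np.ndarray,
    feature_names: list[str] | None = None,
    covariate_names: list[str] = ("age", "sex"),
) -> NormativeResults:
    """Functional form of ``NormativeModel(...).fit()``."""
    return NormativeModel(Y, X, feature_names, covariate_names).fit()


def centile_scores(
    ref: NormativeResults, Y: np.ndarray, X: np.ndarray
) -> np.ndarray:
    """Functional form of :meth:`NormativeResults.centile_scores`."""
    return ref.centile_scores(Y, X)


@dataclass
class CentileTable:
    """Per-subject, per-feature centiles with subject metadata."""

    centiles: np.ndarray  # (n, G), all strictly in (0, 1)
    sites: np.ndarray
    feature_names: list[str]
    harmonized: bool
    diagnosis: np.ndarray | None = None
    is_control: np.ndarray | None = None

    def __post_init__(self) -> None:
        if ((self.centiles <= 0) | (self.centiles >= 1)).any():
            raise DataValidationError("centiles must lie strictly in (0, 1)")

    def to_frame(self) -> pd.DataFrame:
        d: dict = {"site": self.sites, "harmonized": self.harmonized}
        if self.diagnosis is not None:
            d["diagnosis"] = self.diagnosis
        if self.is_control is not None:
            d["is_control"] = self.is_control
        for g, f in enumerate(self.feature_names):
            d[f] = self.centiles[:, g]
        return pd.DataFrame(d)

    def subset(self, mask: np.ndarray) -> "CentileTable":
        mask = np.asarray(mask, dtype=bool)
        return CentileTable(
            centiles=self.centiles[mask],
            sites=self.sites[mask],
            feature_names=self.feature_names,
            harmonized=self.harmonized,
            diagnosis=None if self.diagnosis is None else self.diagnosis[mask],
            is_control=None if self.is_control is None else self.is_control[mask],
        )


def score_new_cohort(
    fit: CombatResults,
    ref: NormativeResults,
    Y_test: np.ndarray,
    X_test: np.ndarray,
    sites_test: np.ndarray,
    controls_mask: np.ndarray,
    X_norm: np.ndarray | None = None,
    diagnosis: np.ndarray | None = None,
    min_controls: int | None = None,
) -> tuple[CentileTable, CentileTable]:
    """Centile-score a new multi-site cohort against a stored reference.

    Per test site: estimate site effects from the site's CONTROL subjects
    only (out-of-sample, from the stored harmonization fit), apply the
    adjustment to all subjects of the site, then score the harmonized and
    the unharmonized values against the same normative reference.  Sites
    with fewer controls than ``min_controls`` (default: the fit's
    ``min_site_n``) are skipped with a logged reason.

    ``X_test`` must match the harmonization fit's covariates; ``X_norm``
    (default ``X_test``'s first columns) must match the normative
    reference's covariates (age, sex).
    """
    Y_test = np.atleast_2d(np.asarray(Y_test, dtype=float))
    sites_test = np.asarray(sites_test).astype(str)
    controls_mask = np.asarray(controls_mask, dtype=bool)
    if X_norm is None:
        X_norm = np.atleast_2d(np.asarray(X_test, dtype=float))[
            :, : len(ref.covariate_names)
        ]
    min_controls = fit.config.min_site_n if min_controls is None else min_controls
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))

    Y_harm = np.full_like(Y_test, np.nan)
    kept = np.zeros(len(Y_test), dtype=bool)
    for lab in sorted(set(sites_test.tolist())):
        mask = sites_test == lab
        n_ctrl = int((mask & controls_mask).sum())
        if n_ctrl < min_controls:
            logger.warning(
                "site %s skipped: %d controls < required %d", lab, n_ctrl, min_controls
            )
            continue
        _, harm = fit.predict_new_site(
            Y_test[mask],
            X_test[mask],
            site_label=lab,
            estimation_mask=controls_mask[mask],
        )
        Y_harm[mask] = harm
        kept |= mask
    if not kept.any():
        raise HarmonizationError("no test site had enough control subjects")

    def _table(values: np.ndarray, harmonized: bool) -> CentileTable:
        return CentileTable(
            centiles=ref.centile_scores(values[kept], X_norm[kept]),
            sites=sites_test[kept],
            feature_names=list(ref.feature_names),
            harmonized=harmonized,
            diagnosis=None if diagnosis is None else np.asarray(diagnosis)[kept],
            is_control=controls_mask[kept],
        )

    return _table(Y_harm, True), _table(Y_test, False)


def cohort_comparison(
    centiles_ref: np.ndarray | CentileTable,
    centiles_test: np.ndarray | CentileTable,
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-feature Wilcoxon rank-sum test and rank-biserial effect size.

    The two-sided test uses the normal approximation with tie correction.
    RBC = (#pairs test > ref - #pairs test < ref) / (n_ref * n_test),
    in [-1, 1]; positive means the test group tends higher.  Features where
    every value of both groups is identical are flagged ``degenerate`` with
    RBC = 0 and p = 1.
    """
    if isinstance(centiles_ref, CentileTable):
        if feature_names is None:
            feature_names = centiles_ref.feature_names
        centiles_ref = centiles_ref.centiles
    if isinstance(centiles_test, CentileTable):
        centiles_test = centiles_test.centiles
    A = np.atleast_2d(np.asarray(centiles_ref, dtype=float))
    B = np.atleast_2d(np.asarray(centiles_test, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise DataValidationError("reference and test feature counts differ")
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise DataValidationError("both groups must be nonempty")
    G = A.shape[1]
    if feature_names is None:
        feature_names = [f"feature_{g}" for g in range(G)]
    n1, n2 = A.shape[0], B.shape[0]
    rows = []
    for g in range(G):
        a, b = A[:, g], B[:, g]
        degenerate = np.ptp(np.concatenate([a, b])) == 0
        if degenerate:
            u, p, rbc = n1 * n2 / 2.0, 1.0, 0.0
        else:
            # U counts test-group wins (+ half-ties)
            u, p = stats.mannwhitneyu(b, a, alternative="two-sided", method="asymptotic")
            rbc = 2.0 * u / (n1 * n2) - 1.0
        rows.append(
            {
                "feature": feature_names[g],
                "statistic": float(u),
                "p_value": float(p),
                "rbc": float(rbc),
                "n_ref": n1,
                "n_test": n2,
                "degenerate": bool(degenerate),
            }
        )
    return pd.DataFrame(rows)
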