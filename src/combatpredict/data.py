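"""Input container for multi-site feature matrices.

A :class:`HarmonizationInput` bundles the subjects x features measurement
matrix ``Y`` (e.g. regional cortical thickness in mm), one site/batch label
per subject, and the biological covariate design ``X`` (e.g. age, sex,
diagnosis indicators).  Site labels are kept as strings; subject order is
preserved throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataValidationError

__all__ = ["HarmonizationInput"]


@dataclass
class HarmonizationInput:
    """Observed matrix with site labels and covariates.

    Parameters
    ----------
    Y : ndarray, shape (n_subjects, n_features)
        Feature values in the units of the measure. No missing values.
    sites : ndarray of str, shape (n_subjects,)
        Site/batch label per subject.
    X : ndarray, shape (n_subjects, n_covariates)
        Covariate design (no intercept column; the intercept is implicit in
        the per-feature grand mean). May have zero columns.
    feature_names, covariate_names : list of str
        Column names, recorded for validation against stored fits.
    """

    Y: np.ndarray
    sites: np.ndarray
    X: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2:
            raise DataValidationError("Y must be 2-dimensional (subjects x features)")
        self.sites = np.asarray(self.sites, dtype=object).astype(str)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        if self.X.size == 0:
            self.X = np.empty((self.Y.shape[0], 0))
        if not self.feature_names:
            self.feature_names = [f"feature_{g}" for g in range(self.Y.shape[1])]
        if not self.covariate_names:
            self.covariate_names = [f"x{j}" for j in range(self.X.shape[1])]
        self.feature_names = [str(f) for f in self.feature_names]
        self.covariate_names = [str(c) for c in self.covariate_names]
        n = self.Y.shape[0]
        if self.sites.shape[0] != n or self.X.shape[0] != n:
            raise DataValidationError(
                f"row counts differ: Y has {n}, sites has {self.sites.shape[0]}, "
                f"X has {self.X.shape[0]}"
            )
        if len(self.feature_names) != self.Y.shape[1]:
            raise DataValidationError("feature_names length does not match Y columns")
        if len(self.covariate_names) != self.X.shape[1]:
            raise DataValidationError("covariate_names length does not match X columns")
        if not np.isfinite(self.Y).all():
            bad = np.argwhere(~np.isfinite(self.Y))[0]
            raise DataValidationError(
                f"non-finite value in Y at row {bad[0]}, "
                f"feature '{self.feature_names[bad[1]]}'"
            )
        if not np.isfinite(self.X).all():
            bad = np.argwhere(~np.isfinite(self.X))[0]
            raise DataValidationError(
                f"non-finite value in X at row {bad[0]}, "
                f"covariate '{self.covariate_names[bad[1]]}'"
            )

    # -- basic accessors -------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.Y.shape[0]

    @property
    def n_features(self) -> int:
        return self.Y.shape[1]

    def site_labels(self) -> list[str]:
        """Unique site labels in sorted order."""
        return sorted(set(self.sites.tolist()))

    def site_sizes(self) -> dict[str, int]:
        labels, counts = np.unique(self.sites, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def validate_site_sizes(self, min_site_n: int = 3) -> None:
        """Every site must have at least ``min_site_n`` subjects."""
        small = {s: n for s, n in self.site_sizes().items() if n < min_site_n}
        if small:
            raise DataValidationError(
                f"sites below the minimum size of {min_site_n}: {small}"
            )

    # -- conversions -----------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        site_col: str,
        covariates: list[str] | tuple[str, ...] = (),
        features: list[str] | None = None,
    ) -> "HarmonizationInput":
        """Build from a tidy table: one row per subject.

        ``features`` defaults to every numeric column that is neither the
        site column nor a covariate, in file order.
        """
        if site_col not in df.columns:
            raise DataValidationError(f"site column '{site_col}' not in table")
        covariates = list(covariates)
        for c in covariates:
            if c not in df.columns:
                raise DataValidationError(f"covariate column '{c}' not in table")
        if features is None:
            reserved = {site_col, *covariates}
            features = [
                c
                for c in df.columns
                if c not in reserved and pd.api.types.is_numeric_dtype(df[c])
            ]
        else:
            for f in features:
                if f not in df.columns:
                    raise DataValidationError(f"feature column '{f}' not in table")
        if not features:
            raise DataValidationError("no feature columns identified")
        for block, cols in (("feature", features), ("covariate", covariates)):
            sub = df[cols]
            na = sub.isna()
            if na.to_numpy().any():
                r, c = np.argwhere(na.to_numpy())[0]
                raise DataValidationError(
                    f"missing value at row {r}, {block} column '{cols[c]}'"
                )
        Y = df[features].to_numpy(dtype=float)
        X = df[covariates].to_numpy(dtype=float) if covariates else np.empty((len(df), 0))
        return cls(
            Y=Y,
            sites=df[site_col].to_numpy(),
            X=X,
            feature_names=list(features),
            covariate_names=covariates,
        )

    def to_frame(self, site_col: str = "site") -> pd.DataFrame:
        """Tidy table with site, covariates, then features."""
        d = {site_col: self.sites}
        for j, c in enumerate(self.covariate_names):
            d[c] = self.X[:, j]
        for g, f in enumerate(self.feature_names):
            d[f] = self.Y[:, g]
        return pd.DataFrame(d)
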