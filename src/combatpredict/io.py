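"""Tabular IO and run-configuration plumbing.

CSV dialect is pinned: comma separator, '.' decimal, UTF-8, mandatory
header.  Output tables carry the run configuration and package version as
leading '#' comment lines, which :func:`read_table` skips, so reruns with
identical configuration and inputs are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import HarmonizationInput
from .exceptions import DataValidationError

__all__ = ["RunConfig", "read_table", "write_table"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one run; echoed into every output."""

    seed: int = 0
    min_site_n: int = 3
    eb: bool = True
    tol: float = 1e-6
    max_iter: int = 500
    reference_site: str | None = None
    site_col: str = "site"
    covariates: list[str] = field(default_factory=list)
    features: list[str] | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.min_site_n < 2:
            raise DataValidationError("min_site_n must be at least 2")
        if self.tol <= 0 or self.max_iter < 1:
            raise DataValidationError("tol must be > 0 and max_iter >= 1")

    def header_lines(self) -> list[str]:
        return [
            f"# combatpredict {__version__}",
            f"# config: {json.dumps(asdict(self), sort_keys=True)}",
        ]


def read_table(
    path,
    site_col: str,
    covariates: list[str] | tuple[str, ...] = (),
    features: list[str] | None = None,
) -> HarmonizationInput:
    """Read a subjects-as-rows CSV into a validated input.

    Site labels are kept as strings; feature columns default to all
    non-mapped numeric columns in file order.  Missing or non-numeric cells
    raise with row/column coordinates.
    """
    df = pd.read_csv(path, comment="#", encoding="utf-8", dtype={site_col: str})
    check_cols = list(covariates) + (list(features) if features else [])
    for col in check_cols:
        if col not in df.columns:
            raise DataValidationError(f"column '{col}' not found in {path}")
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            r = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataValidationError(
                f"non-numeric value {df[col].iloc[r]!r} at row {r}, "
                f"column '{col}' of {path}"
            )
        df[col] = coerced
    return HarmonizationInput.from_dataframe(df, site_col, list(covariates), features)


def write_table(df: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    """Write a CSV with the run-configuration comment header."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if config is not None:
            for line in config.header_lines():
                fh.write(line + "\n")
        df.to_csv(fh, index=False)
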