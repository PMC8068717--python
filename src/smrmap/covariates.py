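"""Rurality deciles and the socioeconomic covariate design.

Areas are ranked by population density (persons per km^2) and split into
ten equal-count deciles, decile 1 = most urban (highest density).  The
four socioeconomic covariates (single-person households %, unmarried
adults %, unemployment %, college-educated %) enter the model as
z-scores; the two right-skewed ones (single-person households, education)
are log-transformed first.  The regression design holds an intercept,
nine decile indicators against the most-urban reference, and — in the
adjusted model — the four standardized covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CovariateMatrix",
    "assign_deciles",
    "transform_covariates",
    "build_design",
    "DEFAULT_LOG_COLUMNS",
    "COVARIATE_COLUMNS",
]

COVARIATE_COLUMNS = (
    "single_person_hh_pct",
    "unmarried_pct",
    "unemployment_pct",
    "college_pct",
)
DEFAULT_LOG_COLUMNS = frozenset({"single_person_hh_pct", "college_pct"})


@dataclass(frozen=True)
class CovariateMatrix:
    """Decile labels, standardized covariates and the model design."""

    area_ids: tuple[str, ...]
    deciles: np.ndarray  # int labels 1..n_groups, 1 = most urban
    covariates: pd.DataFrame  # z-scored columns, indexed by area id
    design: np.ndarray
    design_columns: tuple[str, ...]


def assign_deciles(
    density: pd.Series, n_groups: int = 10
) -> pd.Series:
    """Equal-count density groups, label 1 = most urban (highest density).

    Areas are sorted by descending density (ties broken by a stable sort
    on area id) and cut into contiguous groups whose sizes differ by at
    most one; when n is not a multiple of ``n_groups`` the leading groups
    take the extra member (largest-remainder allocation walks the groups
    in order, so sizes are e.g. 3,3,3,2,... for n=23, n_groups=10).
    """
    d = density.astype(float)
    if (d <= 0).any():
        bad = list(d.index[d <= 0])[:5]
        raise ValueError(f"non-positive density for area(s) {bad}")
    n = len(d)
    if n_groups > n:
        raise ValueError(f"n_groups={n_groups} exceeds number of areas {n}")
    # descending density, ties broken deterministically on area id
    order = sorted(d.index, key=lambda a: (-d[a], str(a)))
    base, rem = divmod(n, n_groups)
    sizes = [base + 1 if g < rem else base for g in range(n_groups)]
    labels = np.repeat(np.arange(1, n_groups + 1), sizes)
    out = pd.Series(labels, index=order, name="decile")
    return out.reindex(density.index)


def transform_covariates(
    raw: pd.DataFrame,
    log_columns: frozenset[str] | set[str] = DEFAULT_LOG_COLUMNS,
) -> pd.DataFrame:
    """Natural-log transform the named columns, then z-score every column.

    z-scores use the sample (n-1) standard deviation.  Zero or negative
    values in a log column and zero-variance columns are errors.
    """
    out = {}
    for col in raw.columns:
        x = raw[col].astype(float)
        if col in log_columns:
            bad = x <= 0
            if bad.any():
                area = x.index[bad][0]
                raise ValueError(
                    f"non-positive value in log column {col!r} at area {area!r}"
                )
            x = np.log(x)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {col!r} has zero variance")
        out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=raw.index)


def build_design(
    deciles: pd.Series,
    covariates: pd.DataFrame | None = None,
    reference: int = 1,
    adjusted: bool = False,
    n_groups: int = 10,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Design matrix: intercept + decile indicators (+ covariates if adjusted).

    Indicator columns cover every decile except the ``reference`` (most
    urban by default); the adjusted design appends the z-scored covariate
    columns.  Returns ``(matrix, column_names)``.
    """
    lab = deciles.astype(int)
    if ((lab < 1) | (lab > n_groups)).any():
        bad = sorted(set(lab[(lab < 1) | (lab > n_groups)]))
        raise ValueError(f"decile labels out of range 1..{n_groups}: {bad}")
    cols = [np.ones(len(lab))]
    names = ["intercept"]
    for g in range(1, n_groups + 1):
        if g == reference:
            continue
        cols.append((lab == g).astype(float).to_numpy())
        names.append(f"decile_{g}")
    if adjusted:
        if covariates is None:
            raise ValueError("adjusted design requires covariates")
        for c in covariates.columns:
            cols.append(covariates[c].to_numpy(float))
            names.append(str(c))
    return np.column_stack(cols), tuple(names)


def covariate_matrix(
    area_ids,
    density: pd.Series,
    raw_covariates: pd.DataFrame,
    adjusted: bool = True,
    log_columns=DEFAULT_LOG_COLUMNS,
) -> CovariateMatrix:
    """Convenience constructor running decile assignment, z-scoring and design."""
    dec = assign_deciles(density)
    z = transform_covariates(raw_covariates, log_columns)
    design, names = build_design(dec, z, adjusted=adjusted)
    return CovariateMatrix(
        tuple(str(a) for a in area_ids), dec.to_numpy(), z, design, names
    )
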