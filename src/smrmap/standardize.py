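"""Indirect standardization: reference rates, expected counts, raw SMRs.

Expected counts are obtained by applying national gender- and age-specific
event rates (10-year age bands) to each area's own population structure.
The standardized mortality ratio SMR_i = O_i / E_i compares observed to
expected events.  Dispersion across areas is summarised by the 90%-range
fold difference, the ratio of the 95th to the 5th percentile — robust to
the unstable extremes of small-population areas — and SMRs are binned into
seven map categories symmetric on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceRates",
    "SMRTable",
    "national_rates",
    "expected_counts",
    "raw_smr",
    "range_ratio",
    "fold_difference",
    "categorize_smr",
    "SMR_BIN_EDGES",
    "SMR_BIN_LABELS",
]

# Seven categories symmetric on the log scale: log(0.50) = -log(2.00),
# log(0.67) ~ -log(1.50), log(0.90) ~ -log(1.10).
SMR_BIN_EDGES = (0.50, 0.67, 0.90, 1.10, 1.50, 2.00)
SMR_BIN_LABELS = (
    "<0.50",
    "0.50-<0.67",
    "0.67-<0.90",
    "0.90-<1.10",
    "1.10-<1.50",
    "1.50-<2.00",
    ">=2.00",
)


@dataclass(frozen=True)
class ReferenceRates:
    """Event rates per person-year, indexed by age band (one gender stratum)."""

    bands: tuple[str, ...]
    rates: np.ndarray  # events per person-year, aligned with bands

    def __post_init__(self):
        if len(self.bands) != len(self.rates):
            raise ValueError("bands and rates length mismatch")
        if np.any(np.asarray(self.rates) < 0):
            raise ValueError("negative reference rate")

    def as_series(self) -> pd.Series:
        return pd.Series(self.rates, index=list(self.bands), name="rate")


@dataclass(frozen=True)
class SMRTable:
    """Per-area SMRs; areas with E=0 are flagged undefined."""

    area_ids: tuple[str, ...]
    smr: np.ndarray
    undefined: np.ndarray  # bool mask, True where E == 0
    stratum: str = "all"

    def defined_values(self) -> np.ndarray:
        return self.smr[~self.undefined]

    def to_frame(self) -> pd.DataFrame:
        cat = np.array(
            [
                categorize_smr(v)[1] if not u else -1
                for v, u in zip(self.smr, self.undefined)
            ]
        )
        labels = [SMR_BIN_LABELS[c - 1] if c > 0 else "" for c in cat]
        return pd.DataFrame(
            {
                "area_id": list(self.area_ids),
                "stratum": self.stratum,
                "smr": np.where(self.undefined, np.nan, self.smr),
                "category_label": labels,
                "category_index": cat,
            }
        )


def national_rates(counts: pd.Series, person_years: pd.Series) -> ReferenceRates:
    """Reference rates = pooled count / pooled person-years per age band.

    Both inputs are indexed by age band.  A band with events but zero
    person-years is an error; a band with zero events and zero exposure
    gets rate 0.
    """
    counts = counts.astype(float)
    person_years = person_years.reindex(counts.index)
    if person_years.isna().any():
        missing = list(person_years.index[person_years.isna()])
        raise ValueError(f"person-years missing for bands {missing}")
    bad = (counts > 0) & (person_years <= 0)
    if bad.any():
        raise ValueError(
            f"events with zero person-years in bands {list(counts.index[bad])}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(person_years > 0, counts / person_years, 0.0)
    return ReferenceRates(tuple(str(b) for b in counts.index), np.asarray(rates, float))


def expected_counts(pop: pd.DataFrame, rates: ReferenceRates) -> pd.Series:
    """E_i = sum over bands of person-years_{i,band} * rate_band.

    ``pop`` has areas as rows and age bands as columns (person-years).
    """
    missing = set(rates.bands) - set(map(str, pop.columns))
    extra = set(map(str, pop.columns)) - set(rates.bands)
    if missing or extra:
        raise ValueError(
            f"age-band mismatch between population and rates: "
            f"missing {sorted(missing)}, unexpected {sorted(extra)}"
        )
    mat = pop[list(rates.bands)].to_numpy(float)
    if (mat < 0).any():
        raise ValueError("negative person-years")
    e = mat @ np.asarray(rates.rates, float)
    return pd.Series(e, index=pop.index, name="expected")


def raw_smr(
    observed: np.ndarray | pd.Series,
    expected: np.ndarray | pd.Series,
    area_ids: tuple[str, ...] | None = None,
    stratum: str = "all",
) -> SMRTable:
    """SMR_i = O_i / E_i; E_i = 0 yields an undefined flag, not a value."""
    if area_ids is None:
        if isinstance(observed, pd.Series):
            area_ids = tuple(str(i) for i in observed.index)
        else:
            area_ids = tuple(str(i) for i in range(len(observed)))
    O = np.asarray(observed, float)
    E = np.asarray(expected, float)
    if O.shape != E.shape:
        raise ValueError("observed and expected length mismatch")
    if (O < 0).any() or (E < 0).any():
        raise ValueError("negative counts")
    undefined = E == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        smr = np.where(undefined, np.nan, O / np.where(undefined, 1.0, E))
    return SMRTable(area_ids, smr, undefined, stratum)


def fold_difference(q_lower: float, q_upper: float) -> tuple[float, float]:
    """Ratio of an upper to a lower quantile, raw and rounded.

    Returns ``(raw, rounded)`` where ``rounded`` is the ratio rounded
    half-up to one decimal (the convention that reproduces printed fold
    values such as 1.31/0.79 = 1.658... -> 1.7).
    """
    if q_lower <= 0:
        raise ValueError("lower quantile must be positive")
    raw = float(q_upper) / float(q_lower)
    rounded = float(Decimal(repr(raw)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return raw, rounded


def range_ratio(
    values: np.ndarray, lower: float = 0.05, upper: float = 0.95
) -> dict[str, float]:
    """90%-range fold difference of a vector of SMRs.

    Quantiles use linear interpolation between order statistics (the
    ubiquitous "type 7" convention).  Returns the two quantiles and the
    raw and 1-decimal rounded fold difference.
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least two defined values")
    q_lo, q_hi = np.quantile(v, [lower, upper])  # linear interpolation default
    raw, rounded = fold_difference(q_lo, q_hi)
    return {
        "q_lower": float(q_lo),
        "q_upper": float(q_hi),
        "fold": raw,
        "fold_rounded": rounded,
    }


def categorize_smr(value: float) -> tuple[str, int]:
    """Map an SMR to its 7-bin map category ``(label, ordinal 1-7)``.

    Bins are left-closed/right-open except the two open extremes:
    <0.50, 0.50-<0.67, 0.67-<0.90, 0.90-<1.10, 1.10-<1.50, 1.50-<2.00, >=2.00.
    """
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"SMR must be finite and non-negative, got {value!r}")
    idx = int(np.searchsorted(SMR_BIN_EDGES, value, side="right"))
    return SMR_BIN_LABELS[idx], idx + 1
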