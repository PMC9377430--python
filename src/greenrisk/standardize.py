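"""Indirect standardization: stratum rates, expected counts, and SIRs.

The expected count for region i in a (sex, age-group) stratum is the count
the region would see if the study-wide stratum rate applied to its own
population:

    rate(sex, age) = sum_i O_i / sum_i pop_i        (over the stratum)
    E_i            = rate(sex, age) * pop_i

Internal standardization implies the closure identity
``sum_i E_i = sum_i O_i`` within each stratum, and a population-weighted
mean standardized incidence ratio (SIR = O/E) of exactly 1.  An external
rate table can replace the internal rates when reference rates exist.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["SEXES", "AGE_GROUPS", "validate_stratum_table", "stratum_rate",
           "expected", "sir"]

SEXES = ("male", "female")
AGE_GROUPS = ("0-19", "20-44", "45-64", ">=65")

_COLUMNS = ["region_id", "sex", "age_group", "population", "observed"]


class DegenerateStratumError(ValueError):
    """A stratum with zero total population has no defined rate."""


def validate_stratum_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the StratumTable schema and invariants; return a clean copy."""
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"StratumTable missing columns {missing}")
    df = df[_COLUMNS].copy()
    if df.duplicated(["region_id", "sex", "age_group"]).any():
        raise ValueError("duplicate (region, sex, age_group) rows")
    if (df["population"] < 0).any() or (df["observed"] < 0).any():
        raise ValueError("populations and counts must be nonnegative")
    if (df["observed"] > df["population"]).any():
        raise ValueError("observed counts exceed population")
    return df


def stratum_rate(counts: pd.DataFrame, sex: str, age_group: str) -> float:
    """Study-wide rate for one (sex, age-group) stratum, cases per person."""
    counts = validate_stratum_table(counts)
    sub = counts[(counts["sex"] == sex) & (counts["age_group"] == age_group)]
    pop = sub["population"].sum()
    if pop <= 0:
        raise DegenerateStratumError(
            f"stratum ({sex}, {age_group}) has zero total population"
        )
    return float(sub["observed"].sum() / pop)


def expected(counts: pd.DataFrame, rates: dict | None = None) -> pd.DataFrame:
    """ExpectedTable with per-row E_i = stratum rate x population.

    ``rates`` optionally maps ``(sex, age_group) -> rate`` for external
    standardization; by default internal (study-area) rates are used, in
    which case closure ``sum E = sum O`` holds per stratum.  Rows with
    zero population get E = 0 and are flagged for exclusion from modeling.
    """
    counts = validate_stratum_table(counts)
    out = counts.copy()
    rate_col = np.empty(len(out))
    for (sex, ag), idx in out.groupby(["sex", "age_group"]).groups.items():
        if rates is not None:
            r = rates[(sex, ag)]
        else:
            r = stratum_rate(counts, sex, ag)
        rate_col[out.index.get_indexer(idx)] = r
    out["expected"] = rate_col * out["population"]
    n_zero = int((out["population"] == 0).sum())
    if n_zero:
        excl = out.loc[out["population"] == 0, "region_id"].tolist()
        logger.warning("%d zero-population row(s) flagged for exclusion: %s",
                       n_zero, excl[:10])
    return out


def sir(observed, expected_counts) -> np.ndarray:
    """Standardized incidence ratio O/E; E=0 entries come back NaN with a warning."""
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected_counts, dtype=float)
    if o.shape != e.shape:
        raise ValueError("observed and expected must align")
    out = np.divide(o, e, out=np.full_like(o, np.nan), where=e > 0)
    n_bad = int((~(e > 0)).sum())
    if n_bad:
        logger.warning("%d region(s) with E=0 excluded from SIR", n_bad)
    return out
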