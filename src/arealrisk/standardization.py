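"""Indirect standardization: expected counts, SIRs, exact intervals.

The observed count Y_i in area i is modelled as Poisson with mean
E_i * theta_i, where the expected count E_i is the dot product of the
area's stratified population P_i with stratum-specific reference rates
psi (estimated from a large reference region, or from the pooled study
itself).  The maximum-likelihood estimate of the relative risk theta_i
is the standardized incidence ratio SIR = Y_i / E_i.  Because DA-scale
counts are small, intervals are exact Poisson (gamma-quantile) rather
than normal approximations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

STRATUM_KEYS = ("age_band", "sex", "income_quintile")


def _keys_of(df: pd.DataFrame) -> list[str]:
    return [c for c in STRATUM_KEYS if c in df.columns]


def estimate_reference_rates(reference: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum rates pooled over all areas: total cases / total persons.

    Strata with zero population (and zero cases) get rate 0 with a
    warning; zero population with positive cases is impossible data.
    """
    keys = _keys_of(reference)
    if reference.empty:
        return pd.DataFrame(columns=list(keys) + ["rate"])
    g = reference.groupby(keys, as_index=False, observed=True)[["population", "cases"]].sum()
    bad = (g["population"] == 0) & (g["cases"] > 0)
    if bad.any():
        raise ValueError(f"strata with cases but no population: {g[bad][keys].to_dict('records')}")
    zero = g["population"] == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} strata have zero population; their rate is set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        g["rate"] = np.where(zero, 0.0, g["cases"] / g["population"])
    return g.drop(columns=["population", "cases"])


def expected_counts(
    population: pd.DataFrame, rates: pd.DataFrame, strict: bool = True
) -> pd.Series:
    """E_i = sum over strata of persons x reference rate, per area.

    When the rate vector is income-stratified the result is an
    income-adjusted expectation; with age-sex rates only, income is
    ignored even if present in the population table.
    """
    keys = _keys_of(rates)
    missing_cols = [k for k in keys if k not in population.columns]
    if missing_cols:
        raise KeyError(f"population table lacks stratum column(s) {missing_cols}")
    df = population.merge(rates, on=keys, how="left", validate="many_to_one")
    if df["rate"].isna().any():
        missing = df[df["rate"].isna()][keys].drop_duplicates().to_dict("records")
        if strict:
            raise KeyError(f"strata missing from rate vector: {missing}")
        warnings.warn(f"imputing rate 0 for strata missing from rate vector: {missing}")
        df["rate"] = df["rate"].fillna(0.0)
    df["_e"] = df["population"] * df["rate"]
    return df.groupby("area_id", observed=True)["_e"].sum().rename("expected")


def observed_counts(strata: pd.DataFrame) -> pd.Series:
    """Y_i = total cases per area."""
    return strata.groupby("area_id", observed=True)["cases"].sum().rename("observed")


def sir_confidence_interval(y: int, e: float, level: float = 0.95) -> tuple[float, float]:
    """Exact Poisson interval for theta = mean/E via gamma quantiles.

    Lower limit is 0 when no cases are observed; the upper limit uses
    the gamma(y+1) quantile, i.e. the exact Poisson tail inversion.
    """
    if e <= 0:
        raise ValueError("expected count must be > 0 for an interval")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    a = (1.0 - level) / 2.0
    low = 0.0 if y == 0 else stats.gamma.ppf(a, y) / e
    high = stats.gamma.ppf(1.0 - a, y + 1) / e
    return float(low), float(high)


def compute_sir(
    strata: pd.DataFrame, rates: pd.DataFrame, level: float = 0.95, strict: bool = True
) -> pd.DataFrame:
    """Per-area risk table: observed, expected, SIR, exact interval.

    Areas with E = 0 and Y = 0 are retained but flagged ``excluded``
    (they carry no information and are dropped from the Moran and BYM
    stages); E = 0 with Y > 0 is impossible under the model and raises.
    """
    e = expected_counts(strata, rates, strict=strict)
    y = observed_counts(strata)
    tab = pd.concat([y, e], axis=1).reset_index()
    bad = (tab["expected"] == 0) & (tab["observed"] > 0)
    if bad.any():
        raise ValueError(
            f"areas with observed cases but zero expected count: {tab[bad]['area_id'].tolist()}"
        )
    tab["excluded"] = tab["expected"] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        tab["sir"] = np.where(tab["excluded"], np.nan, tab["observed"] / tab["expected"])
    lows, highs = [], []
    for yy, ee, ex in zip(tab["observed"], tab["expected"], tab["excluded"]):
        if ex:
            lows.append(np.nan)
            highs.append(np.nan)
        else:
            lo, hi = sir_confidence_interval(int(yy), float(ee), level)
            lows.append(lo)
            highs.append(hi)
    tab["ci_low"] = lows
    tab["ci_high"] = highs
    return tab[["area_id", "observed", "expected", "sir", "ci_low", "ci_high", "excluded"]]


def aggregate_sir(
    risk_table: pd.DataFrame,
    subset: list[str],
    level: float = 0.95,
    reference: str = "external",
) -> dict:
    """Combined SIR over a set of areas.

    ``reference='external'`` keeps the original expectations;
    ``reference='complement'`` rescales the subset's E by the
    complement's observed/expected ratio, giving risk *relative to the
    remainder of the study region* (the convention used when reporting
    cluster SIRs against the rest of the study area).
    """
    if not subset:
        raise ValueError("area subset must be non-empty")
    subset_set = set(subset)
    unknown = subset_set - set(risk_table["area_id"])
    if unknown:
        raise KeyError(f"unknown area(s) in subset: {sorted(unknown)}")
    inside = risk_table[risk_table["area_id"].isin(subset_set)]
    y = int(inside["observed"].sum())
    e = float(inside["expected"].sum())
    if reference == "complement":
        outside = risk_table[~risk_table["area_id"].isin(subset_set)]
        y_out, e_out = outside["observed"].sum(), outside["expected"].sum()
        if e_out <= 0 or y_out <= 0:
            raise ValueError("complement has no informative areas")
        e = e * (y_out / e_out)
    if e <= 0:
        raise ValueError("combined expected count is zero")
    lo, hi = sir_confidence_interval(y, e, level)
    return {
        "observed": y,
        "expected": e,
        "sir": y / e,
        "ci_low": lo,
        "ci_high": hi,
        "level": level,
        "reference": reference,
    }
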