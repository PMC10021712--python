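"""Indirect standardization: expected deaths and raw SMRs at any tier.

A region's expected deaths are obtained by applying national age-specific
mortality rates, per calendar year, to the region's age-stratified population
and summing over the full multi-year window.  The raw SMR is the observed to
expected ratio on the x100 convention: SMR = 100 means the region's risk
equals the national average.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TIERS = ("unit", "middle", "top")

REGION_TABLE_COLUMNS = ["region_id", "tier", "deaths", "expected", "raw_smr"]


def reference_rates_from_counts(counts: pd.DataFrame,
                                per_year: bool = True) -> pd.DataFrame:
    """National age-specific rates from pooled counts.

    Used when no external reference table is supplied: the analyzed slice is
    its own standard, which makes the standardization identity
    (sum of expected = national observed deaths) hold exactly.

    ``per_year=True`` (default) computes a rate for every (year, stratum);
    ``per_year=False`` pools the whole window into one rate per stratum,
    replicated across years — a sensitivity-check alternative.
    """
    nat = counts.groupby(["year", "age_stratum"], as_index=False)[
        ["deaths", "population"]
    ].sum()
    if not per_year:
        pooled = nat.groupby("age_stratum")[["deaths", "population"]].transform("sum")
        nat[["deaths", "population"]] = pooled
    nat = nat.rename(columns={"deaths": "national_deaths",
                              "population": "national_population"})
    with np.errstate(invalid="ignore", divide="ignore"):
        nat["rate"] = np.where(nat["national_population"] > 0,
                               nat["national_deaths"] / nat["national_population"], 0.0)
    return nat


def read_rates(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if "rate" not in df.columns:
        if {"national_deaths", "national_population"} <= set(df.columns):
            df["rate"] = df["national_deaths"] / df["national_population"]
        else:
            raise ValueError(f"{path}: need a 'rate' column or national counts")
    return df


def expected_deaths(counts: pd.DataFrame, rates: pd.DataFrame) -> pd.Series:
    """Per-region expected deaths e_i = sum_y sum_s rate(y, s) * pop(i, y, s).

    Unknown-age records must already have been dropped.  Every (year, stratum)
    present in ``counts`` must have a reference rate.
    """
    merged = counts.merge(rates[["year", "age_stratum", "rate"]],
                          on=["year", "age_stratum"], how="left", validate="m:1")
    miss = merged.loc[merged["rate"].isna(), ["year", "age_stratum"]].drop_duplicates()
    if len(miss):
        raise ValueError(
            "missing reference rate for (year, age_stratum): "
            f"{list(miss.itertuples(index=False, name=None))[:10]}"
        )
    merged["_e"] = merged["rate"] * merged["population"]
    e = merged.groupby("region_id", sort=True)["_e"].sum()
    e.name = "expected"
    return e


def raw_smr(d, e):
    """Raw SMR = 100 * d / e; NaN (undefined) where e = 0."""
    d = np.asarray(d, dtype=float)
    e = np.asarray(e, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(e > 0, 100.0 * d / e, np.nan)
    return float(out) if out.ndim == 0 else out


def make_region_table(counts: pd.DataFrame, rates: pd.DataFrame | None = None,
                      tier: str = "unit") -> pd.DataFrame:
    """Build the per-region table of deaths, expected deaths and raw SMR.

    If ``rates`` is None the slice standardizes against itself
    (:func:`reference_rates_from_counts`).
    """
    if rates is None:
        rates = reference_rates_from_counts(counts)
    e = expected_deaths(counts, rates)
    d = counts.groupby("region_id", sort=True)["deaths"].sum()
    tbl = pd.DataFrame({
        "region_id": e.index,
        "tier": tier,
        "deaths": d.reindex(e.index).fillna(0).astype(int).to_numpy(),
        "expected": e.to_numpy(),
    })
    tbl["raw_smr"] = raw_smr(tbl["deaths"], tbl["expected"])
    n_undef = int(tbl["raw_smr"].isna().sum())
    if n_undef:
        logger.info("%d region(s) with zero expected deaths: raw SMR undefined", n_undef)
    return tbl


def aggregate_tier(table: pd.DataFrame, hierarchy: pd.DataFrame,
                   target_tier: str) -> pd.DataFrame:
    """Roll a unit-tier region table up to the middle or top tier.

    Deaths and expected deaths are summed over constituent units and the raw
    SMR is recomputed from the sums (never averaged).
    """
    if target_tier not in ("middle", "top"):
        raise ValueError(f"target_tier must be 'middle' or 'top', got {target_tier!r}")
    key = f"{target_tier}_id"
    mapping = hierarchy.set_index("unit_id")[key]
    unknown = sorted(set(table["region_id"]) - set(mapping.index))
    if unknown:
        raise ValueError(f"unit(s) absent from hierarchy: {unknown[:10]}")
    grp = table.copy()
    grp["region_id"] = grp["region_id"].map(mapping)
    agg = grp.groupby("region_id", as_index=False, sort=True)[["deaths", "expected"]].sum()
    agg.insert(1, "tier", target_tier)
    agg["raw_smr"] = raw_smr(agg["deaths"], agg["expected"])
    return agg


def write_region_table(table: pd.DataFrame, path,
                       header_lines: list[str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        table.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")


def read_region_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"region_id": str})
    missing = set(REGION_TABLE_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: region table missing column(s) {sorted(missing)}")
    return df
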