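"""Indirect age/sex standardization of areal case counts.

Expected counts per area are obtained by applying reference (national)
stratum-specific incidence rates to the area's stratum person-years:

    E_i = sum_s n_{i,s} * r_s,      r_s = (sum_i O_{i,s}) / (sum_i n_{i,s})

When the reference rates are computed from the analyzed table itself
("internal" standardization, the convention here), the identity
sum_i E_i = sum_i O_i holds exactly.  The raw parish-to-national incidence
rate ratio is IRR_i = O_i / E_i; it is unstable for small areas, which is why
the spatial model in :mod:`carmap.model` smooths it.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SEXES",
    "AGE_GROUPS",
    "STRATA",
    "StratifiedAreaTable",
    "ReferenceRates",
    "compute_reference_rates",
    "expected_counts",
    "raw_irr",
]

SEXES = ("male", "female")
#: Seven age groups with inclusive upper edges; together with sex they define
#: the 14 standardization strata.
AGE_GROUPS = ("<=40", "41-50", "51-60", "61-70", "71-80", "81-90", ">90")
STRATA = tuple((sex, ag) for sex in SEXES for ag in AGE_GROUPS)

_COLUMNS = ["area_id", "sex", "age_group", "person_years", "cases"]


class StratifiedAreaTable:
    """Long-format per-area, per-stratum person-years and observed cases.

    Wraps a DataFrame with columns ``area_id, sex, age_group, person_years,
    cases`` (one row per area-stratum).  Missing area-stratum rows are treated
    as zero person-years and zero cases.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"table lacks columns: {missing}")
        df = df[_COLUMNS].copy()
        df["area_id"] = df["area_id"].astype(str)
        bad_sex = set(df["sex"]) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex values: {sorted(bad_sex)}")
        bad_ag = set(df["age_group"]) - set(AGE_GROUPS)
        if bad_ag:
            raise ValueError(f"unknown age groups: {sorted(bad_ag)}")
        if (df["person_years"] < 0).any():
            raise ValueError("negative person-years")
        if (df["cases"] < 0).any():
            raise ValueError("negative case counts")
        viol = df[(df["person_years"] == 0) & (df["cases"] > 0)]
        if len(viol):
            raise ValueError(
                f"cases recorded in strata with zero person-years ({len(viol)} rows)")
        if df.duplicated(subset=["area_id", "sex", "age_group"]).any():
            raise ValueError("duplicate area-stratum rows")
        self.df = df.reset_index(drop=True)

    @property
    def area_ids(self) -> list[str]:
        """Area identifiers in first-appearance order."""
        return list(dict.fromkeys(self.df["area_id"]))

    def observed_by_area(self) -> pd.Series:
        """O_i = total observed cases per area."""
        return self.df.groupby("area_id", sort=False)["cases"].sum()

    def person_years_by_area(self) -> pd.Series:
        return self.df.groupby("area_id", sort=False)["person_years"].sum()

    def pooled(self) -> pd.DataFrame:
        """Per-stratum national totals: sum over areas of person-years and cases."""
        return (self.df.groupby(["sex", "age_group"], sort=False)[["person_years", "cases"]]
                .sum().reset_index())

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StratifiedAreaTable":
        return cls(pd.read_csv(path, dtype={"area_id": str}))

    def __len__(self) -> int:
        return len(self.df)


class ReferenceRates:
    """Per-stratum reference incidence rates, stored per person-year.

    The per-100 000 person-years scale is for display and I/O only; all
    computation uses per-person-year rates to avoid silent unit mix-ups.
    """

    def __init__(self, rates: Mapping[tuple[str, str], float]):
        missing = [s for s in STRATA if s not in rates]
        if missing:
            raise ValueError(f"missing strata in reference rates: {missing[:3]}")
        neg = {s: r for s, r in rates.items() if r < 0}
        if neg:
            raise ValueError(f"negative rates: {neg}")
        self.rates = {s: float(rates[s]) for s in STRATA}

    def __getitem__(self, stratum: tuple[str, str]) -> float:
        return self.rates[stratum]

    def per_100k(self) -> pd.DataFrame:
        """Display table with column ``rate_per_100k``."""
        return pd.DataFrame(
            [{"sex": s, "age_group": a, "rate_per_100k": self.rates[(s, a)] * 1e5}
             for s, a in STRATA])

    def to_csv(self, path) -> None:
        self.per_100k().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReferenceRates":
        df = pd.read_csv(path)
        return cls({(r.sex, r.age_group): r.rate_per_100k / 1e5 for r in df.itertuples()})

    @classmethod
    def from_per_100k(cls, rates_100k: Mapping[tuple[str, str], float]) -> "ReferenceRates":
        return cls({s: r / 1e5 for s, r in rates_100k.items()})


def compute_reference_rates(pooled: StratifiedAreaTable) -> ReferenceRates:
    """National stratum rates r_s = total cases / total person-years.

    Raises a domain error naming the stratum if any stratum has zero
    person-years overall (its rate would be undefined).
    """
    totals = pooled.pooled().set_index(["sex", "age_group"])
    rates = {}
    for sex, ag in STRATA:
        if (sex, ag) in totals.index:
            py = totals.loc[(sex, ag), "person_years"]
            cases = totals.loc[(sex, ag), "cases"]
        else:
            py, cases = 0.0, 0.0
        if py <= 0:
            raise ValueError(f"stratum ({sex}, {ag}) has zero person-years; rate undefined")
        rates[(sex, ag)] = cases / py
    return ReferenceRates(rates)


def expected_counts(table: StratifiedAreaTable, rates: ReferenceRates) -> pd.Series:
    """Indirectly standardized expected counts E_i = sum_s n_{i,s} r_s.

    Returns a Series indexed by ``area_id`` in the table's area order.  With
    internally computed rates, sum(E) equals sum(O) exactly (up to float
    round-off).
    """
    keys = list(zip(table.df["sex"], table.df["age_group"]))
    r = np.array([rates[k] for k in keys])
    contrib = table.df["person_years"].to_numpy() * r
    e = pd.Series(contrib, index=table.df["area_id"]).groupby(level=0, sort=False).sum()
    return e.reindex(table.area_ids)


def raw_irr(observed: pd.Series, expected: pd.Series) -> pd.Series:
    """Raw incidence rate ratio IRR_i = O_i / E_i.

    Areas with E_i = 0 are excluded from the result with a logged warning
    (the ratio is undefined there).
    """
    observed, expected = observed.align(expected, join="inner")
    zero = expected == 0
    if zero.any():
        logger.warning("excluding %d area(s) with zero expected counts from raw IRR",
                       int(zero.sum()))
    keep = ~zero
    return observed[keep] / expected[keep]
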