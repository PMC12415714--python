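"""Synthetic registry generator for small-area disease mapping.

The motivating application — parish-level mapping of pleural mesothelioma in
Denmark — rests on individual-level cancer-registry data that cannot be
shared.  This module generates a synthetic stand-in with the same shape so
that the whole pipeline is testable end to end:

* a geography (regular lattice with rook adjacency, or any supplied graph)
  whose area populations mimic the heavy-tailed Danish parish-size
  distribution (31 to 46 586 inhabitants, median near 1039);
* stratified person-years over the 14 age-by-sex standardization strata,
  accumulated over a multi-year observation window (default 32 years,
  matching a 1990-2021 registry extract);
* a spatially correlated log-relative-risk surface drawn from the Leroux
  Gaussian Markov random field, optionally with implanted hotspot areas of
  known excess risk;
* stratum-level Poisson case counts and individual pseudo-registry records
  carrying ICD-10 / ICD-O-3 codes, including non-qualifying "decoy" records,
  so the case-definition filter has something to reject.

Every generator is deterministic given its seed, and a single dataset-level
seed is split into independent substreams per stage, so adding a stage never
perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .geography import AdjacencyGraph, leroux_precision
from .standardization import AGE_GROUPS, SEXES, STRATA, ReferenceRates, StratifiedAreaTable

__all__ = [
    "DEFAULT_RATES_PER_100K",
    "DEFAULT_STRATUM_FRACTIONS",
    "QUALIFYING_MORPHOLOGIES",
    "GeographySpec",
    "RiskSurfaceTruth",
    "make_lattice_geography",
    "simulate_person_years",
    "sample_leroux_gmrf",
    "simulate_counts",
    "simulate_stratified_counts",
    "implant_hotspot",
    "make_risk_surface",
    "simulate_registry_records",
    "apply_case_definition",
    "assign_age_group",
    "tabulate_cases",
    "simulate_dataset",
]

#: Danish national pleural-mesothelioma incidence rates per 100 000
#: person-years by sex and age group (1990-2021 registry period); the
#: generator's default calibration.
DEFAULT_RATES_PER_100K: dict[tuple[str, str], float] = {
    ("male", "<=40"): 0.02, ("male", "41-50"): 0.67, ("male", "51-60"): 3.30,
    ("male", "61-70"): 9.48, ("male", "71-80"): 16.84, ("male", "81-90"): 14.13,
    ("male", ">90"): 3.26,
    ("female", "<=40"): 0.02, ("female", "41-50"): 0.17, ("female", "51-60"): 0.63,
    ("female", "61-70"): 1.53, ("female", "71-80"): 2.16, ("female", "81-90"): 2.22,
    ("female", ">90"): 1.01,
}

# Age composition loosely shaped like the Danish population pyramid; split
# evenly between the sexes.  Sums to 1 exactly.
_AGE_FRACTIONS = {"<=40": 0.48, "41-50": 0.14, "51-60": 0.13, "61-70": 0.11,
                  "71-80": 0.09, "81-90": 0.04, ">90": 0.01}
DEFAULT_STRATUM_FRACTIONS: dict[tuple[str, str], float] = {
    (sex, ag): 0.5 * _AGE_FRACTIONS[ag] for sex in SEXES for ag in AGE_GROUPS}

#: ICD-O-3 morphology codes that qualify a C38.4 diagnosis as mesothelioma.
QUALIFYING_MORPHOLOGIES = frozenset({"M9050/3", "M9051/3", "M9052/3", "M9053/3"})

# Non-qualifying code pairs used for decoy records; only the filter's
# decision boundary matters, so a fixed small list suffices.
_DECOY_CODES: list[tuple[str, str | None]] = [
    ("C45.1", None),            # peritoneal mesothelioma
    ("C45.2", "M9050/3"),       # pericardial site, right morphology, wrong site code
    ("C38.4", "M8140/3"),       # pleural site, adenocarcinoma morphology
    ("C38.4", None),            # pleural site, morphology missing
    ("C34.9", "M9051/3"),       # lung site, mesothelioma morphology
]

_AGE_BOUNDS = {"<=40": (0, 40), "41-50": (41, 50), "51-60": (51, 60),
               "61-70": (61, 70), "71-80": (71, 80), "81-90": (81, 90),
               ">90": (91, 105)}


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class GeographySpec:
    """Target shape of a synthetic geography's population distribution."""

    n_areas: int
    population_range: tuple[int, int] = (31, 46586)
    median_population_target: int = 1039

    def __post_init__(self):
        lo, hi = self.population_range
        if self.n_areas < 1:
            raise ValueError("n_areas must be positive")
        if lo < 1 or hi < lo:
            raise ValueError("population_range must satisfy 1 <= min <= max")
        if not lo <= self.median_population_target <= hi:
            raise ValueError("median target must lie within population_range")


@dataclass(frozen=True)
class RiskSurfaceTruth:
    """Ground-truth risk surface used to simulate counts and score recovery."""

    area_ids: tuple[str, ...]
    beta_true: float
    phi_true: np.ndarray
    rho_true: float
    tau2_true: float
    hotspot_areas: frozenset[str] = field(default_factory=frozenset)
    hotspot_multiplier: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "phi_true", np.asarray(self.phi_true, dtype=float))
        if len(self.phi_true) != len(self.area_ids):
            raise ValueError("phi_true length must equal number of areas")
        if not 0.0 <= self.rho_true <= 1.0:
            raise ValueError("rho_true must lie in [0, 1]")
        if self.tau2_true <= 0:
            raise ValueError("tau2_true must be positive")

    def relative_risk(self) -> np.ndarray:
        """exp(beta + phi) per area: the true incidence rate ratio surface."""
        return np.exp(self.beta_true + self.phi_true)

    def to_json(self, path) -> None:
        obj = {"area_ids": list(self.area_ids), "beta_true": self.beta_true,
               "phi_true": self.phi_true.tolist(), "rho_true": self.rho_true,
               "tau2_true": self.tau2_true,
               "hotspot_areas": sorted(self.hotspot_areas),
               "hotspot_multiplier": self.hotspot_multiplier}
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RiskSurfaceTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(area_ids=tuple(obj["area_ids"]), beta_true=obj["beta_true"],
                   phi_true=np.array(obj["phi_true"]), rho_true=obj["rho_true"],
                   tau2_true=obj["tau2_true"],
                   hotspot_areas=frozenset(obj["hotspot_areas"]),
                   hotspot_multiplier=obj["hotspot_multiplier"])


def make_lattice_geography(nx: int, ny: int) -> AdjacencyGraph:
    """nx-by-ny rook-adjacency lattice standing in for an administrative map."""
    return AdjacencyGraph.lattice(nx, ny)


def simulate_person_years(spec: GeographySpec,
                          stratum_fractions: Mapping[tuple[str, str], float] | None = None,
                          years: int = 32,
                          seed=0,
                          area_ids: Sequence[str] | None = None) -> StratifiedAreaTable:
    """Generate per-area, per-stratum person-years (cases set to zero).

    Area populations are drawn log-uniformly over ``spec.population_range``
    and rescaled multiplicatively so the realized median matches the target,
    mimicking the heavy right tail of parish sizes.  Person-years are
    population times ``years``, apportioned exactly across strata by the
    given fractions (defaults to a Danish-like age/sex pyramid).
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    fractions = dict(stratum_fractions) if stratum_fractions is not None \
        else dict(DEFAULT_STRATUM_FRACTIONS)
    vals = np.array([fractions.get(s, 0.0) for s in STRATA])
    if (vals < 0).any():
        raise ValueError("stratum fractions must be nonnegative")
    if abs(vals.sum() - 1.0) > 1e-9:
        raise ValueError(f"stratum fractions must sum to 1, got {vals.sum():.12f}")

    rng = _rng(seed)
    lo, hi = spec.population_range
    pops = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_areas))
    med = np.median(pops)
    if med > 0:
        pops = np.clip(pops * (spec.median_population_target / med), lo, hi)
    pops = np.maximum(np.rint(pops).astype(int), lo)

    if area_ids is None:
        area_ids = [f"A{i:04d}" for i in range(spec.n_areas)]
    elif len(area_ids) != spec.n_areas:
        raise ValueError("area_ids length must equal n_areas")

    rows = []
    for aid, pop in zip(area_ids, pops):
        total_py = float(pop) * years
        for s, frac in zip(STRATA, vals):
            rows.append({"area_id": aid, "sex": s[0], "age_group": s[1],
                         "person_years": total_py * frac, "cases": 0})
    return StratifiedAreaTable(pd.DataFrame(rows))


def sample_leroux_gmrf(graph: AdjacencyGraph, rho: float, tau2: float,
                       seed=0, size: int | None = None) -> np.ndarray:
    """Exact draw(s) from the zero-mean Leroux Gaussian Markov random field.

    The joint precision is Q = [rho*(D - W) + (1 - rho)*I] / tau2, proper for
    rho in [0, 1) and tau2 > 0.  Sampling is by Cholesky factorization
    Q = U'U and back-substitution of standard normals (x = U^{-1} z has
    covariance Q^{-1}).  Returns shape ``(n,)`` or ``(size, n)``.
    """
    Q = leroux_precision(graph, rho, tau2)  # validates rho, tau2
    U = scipy.linalg.cholesky(Q, lower=False)
    rng = _rng(seed)
    z = rng.standard_normal((size or 1, graph.n))
    x = scipy.linalg.solve_triangular(U, z.T, lower=False).T
    return x if size is not None else x[0]


def simulate_counts(expected: np.ndarray, beta: float, phi: np.ndarray, seed=0) -> np.ndarray:
    """Poisson counts O_i ~ Poisson(E_i * exp(beta + phi_i))."""
    expected = np.asarray(expected, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if expected.shape != phi.shape:
        raise ValueError("expected and phi must have matching shapes")
    if (expected < 0).any():
        raise ValueError("expected counts must be nonnegative")
    rng = _rng(seed)
    return rng.poisson(expected * np.exp(beta + phi))


def make_risk_surface(graph: AdjacencyGraph, beta: float = 0.0, rho: float = 0.7,
                      tau2: float = 0.3, seed=0) -> RiskSurfaceTruth:
    """Draw a Leroux-GMRF log-risk surface over ``graph`` as ground truth."""
    phi = sample_leroux_gmrf(graph, rho, tau2, seed=seed)
    return RiskSurfaceTruth(area_ids=tuple(str(a) for a in graph.area_ids),
                            beta_true=beta, phi_true=phi, rho_true=rho, tau2_true=tau2)


def implant_hotspot(truth: RiskSurfaceTruth, areas: Iterable[str],
                    multiplier: float) -> RiskSurfaceTruth:
    """Raise the relative risk of ``areas`` by ``multiplier`` (>= 1).

    phi is increased by log(multiplier) on the hotspot; all other areas are
    untouched.  Returns a new truth object.
    """
    if multiplier < 1:
        raise ValueError("hotspot multiplier must be >= 1")
    areas = {str(a) for a in areas}
    unknown = areas - set(truth.area_ids)
    if unknown:
        raise ValueError(f"unknown area ids: {sorted(unknown)[:5]}")
    phi = truth.phi_true.copy()
    idx = [truth.area_ids.index(a) for a in areas]
    phi[idx] += np.log(multiplier)
    return replace(truth, phi_true=phi,
                   hotspot_areas=truth.hotspot_areas | frozenset(areas),
                   hotspot_multiplier=multiplier)


def simulate_stratified_counts(table: StratifiedAreaTable, truth: RiskSurfaceTruth,
                               rates: ReferenceRates | None = None,
                               seed=0) -> StratifiedAreaTable:
    """Fill the ``cases`` column with O_{i,s} ~ Poisson(n_{i,s} r_s e^{beta+phi_i})."""
    if rates is None:
        rates = ReferenceRates.from_per_100k(DEFAULT_RATES_PER_100K)
    rng = _rng(seed)
    rr = {a: np.exp(truth.beta_true + truth.phi_true[k])
          for k, a in enumerate(truth.area_ids)}
    df = table.df.copy()
    mu = np.array([row.person_years * rates[(row.sex, row.age_group)] * rr[row.area_id]
                   for row in df.itertuples()])
    df["cases"] = rng.poisson(mu)
    return StratifiedAreaTable(df)


def assign_age_group(age: int) -> str:
    """Map an integer age at diagnosis to its standardization age group.

    Bins have inclusive upper edges: 40 -> "<=40", 41 -> "41-50", ...,
    91 -> ">90".  Negative ages are rejected.
    """
    if age < 0:
        raise ValueError("age must be nonnegative")
    if age <= 40:
        return "<=40"
    if age <= 50:
        return "41-50"
    if age <= 60:
        return "51-60"
    if age <= 70:
        return "61-70"
    if age <= 80:
        return "71-80"
    if age <= 90:
        return "81-90"
    return ">90"


def simulate_registry_records(table: StratifiedAreaTable, truth: RiskSurfaceTruth,
                              decoy_fraction: float = 0.0, seed=0,
                              rates: ReferenceRates | None = None,
                              start_year: int = 1990, end_year: int = 2021) -> pd.DataFrame:
    """Individual pseudo-registry records, with qualifying and decoy codes.

    If ``table`` already carries case counts, one record is emitted per
    counted case; otherwise stratum counts are first drawn from ``truth`` via
    :func:`simulate_stratified_counts`.  True cases receive a qualifying code
    combination (mostly the site-specific C45.0, a minority C38.4 plus a
    mesothelioma morphology).  Decoy records with non-qualifying codes are
    added at ``decoy_fraction`` of the true-case count and shuffled in, so
    :func:`apply_case_definition` has a real decision to make.
    """
    if not 0.0 <= decoy_fraction <= 1.0:
        raise ValueError("decoy_fraction must lie in [0, 1]")
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_counts, s_attrs = ss.spawn(2)
    if table.df["cases"].sum() == 0:
        table = simulate_stratified_counts(table, truth, rates=rates,
                                           seed=np.random.default_rng(s_counts))
    rng = np.random.default_rng(s_attrs)

    rows = []
    for row in table.df.itertuples():
        lo, hi = _AGE_BOUNDS[row.age_group]
        for _ in range(int(row.cases)):
            if rng.random() < 0.8:
                icd10, morph = "C45.0", None
                if rng.random() < 0.5:  # morphology often recorded even for C45.0
                    morph = rng.choice(sorted(QUALIFYING_MORPHOLOGIES))
            else:
                icd10 = "C38.4"
                morph = rng.choice(sorted(QUALIFYING_MORPHOLOGIES))
            rows.append({"area_id": row.area_id, "sex": row.sex,
                         "age": int(rng.integers(lo, hi + 1)),
                         "year": int(rng.integers(start_year, end_year + 1)),
                         "icd10": icd10, "morphology": morph})
    n_true = len(rows)
    n_decoy = int(round(decoy_fraction * n_true))
    area_ids = table.area_ids
    for _ in range(n_decoy):
        sex, ag = STRATA[rng.integers(len(STRATA))]
        lo, hi = _AGE_BOUNDS[ag]
        icd10, morph = _DECOY_CODES[rng.integers(len(_DECOY_CODES))]
        rows.append({"area_id": area_ids[rng.integers(len(area_ids))], "sex": sex,
                     "age": int(rng.integers(lo, hi + 1)),
                     "year": int(rng.integers(start_year, end_year + 1)),
                     "icd10": icd10, "morphology": morph})
    df = pd.DataFrame(rows, columns=["area_id", "sex", "age", "year", "icd10", "morphology"])
    if len(df):
        df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df.insert(0, "person_id", [f"P{k:06d}" for k in range(len(df))])
    return df


def apply_case_definition(records: pd.DataFrame) -> pd.DataFrame:
    """Keep records meeting the mesothelioma case definition; order preserved.

    A record qualifies iff its ICD-10 code is C45.0 (any morphology,
    including missing), or C38.4 with an ICD-O-3 morphology in
    {M9050/3, M9051/3, M9052/3, M9053/3}.  Malformed codes simply fail to
    match.  Idempotent.
    """
    if "icd10" not in records.columns:
        raise ValueError("records lack an 'icd10' column")
    icd = records["icd10"].astype(str)
    morph = records["morphology"] if "morphology" in records.columns else pd.Series(
        [None] * len(records), index=records.index)
    keep = (icd == "C45.0") | ((icd == "C38.4") & morph.isin(QUALIFYING_MORPHOLOGIES))
    return records[keep].copy()


def tabulate_cases(records: pd.DataFrame, table: StratifiedAreaTable) -> StratifiedAreaTable:
    """Aggregate filtered registry records into the table's ``cases`` column.

    Applies the case definition first, assigns each record to its age group,
    and counts cases per area-stratum.  Records in areas absent from the
    table raise an error.
    """
    cases = apply_case_definition(records)
    unknown = set(cases["area_id"].astype(str)) - set(table.area_ids)
    if unknown:
        raise ValueError(f"records reference unknown areas: {sorted(unknown)[:5]}")
    df = table.df.copy()
    df["cases"] = 0
    if len(cases):
        grp = (cases.assign(age_group=cases["age"].map(assign_age_group))
               .groupby(["area_id", "sex", "age_group"]).size())
        key = pd.MultiIndex.from_frame(df[["area_id", "sex", "age_group"]])
        df["cases"] = grp.reindex(key, fill_value=0).to_numpy()
    return StratifiedAreaTable(df)


def simulate_dataset(nx: int = 15, ny: int = 15, years: int = 32,
                     beta: float = 0.0, rho: float = 0.7, tau2: float = 0.3,
                     hotspot_areas: Sequence[str] = (), hotspot_multiplier: float = 1.0,
                     decoy_fraction: float = 0.1, seed: int = 0,
                     spec: GeographySpec | None = None) -> dict:
    """End-to-end synthetic study: geography, person-years, risk, registry.

    Returns a dict with keys ``graph``, ``table`` (person-years and cases),
    ``truth``, ``records`` (raw registry including decoys) and ``rates``
    (the generating reference rates).  Substreams are spawned from ``seed``
    stage by stage.
    """
    ss = np.random.SeedSequence(seed)
    s_py, s_phi, s_rec = ss.spawn(3)
    graph = make_lattice_geography(nx, ny)
    if spec is None:
        spec = GeographySpec(n_areas=graph.n)
    table = simulate_person_years(spec, years=years, seed=np.random.default_rng(s_py),
                                  area_ids=graph.area_ids)
    truth = make_risk_surface(graph, beta=beta, rho=rho, tau2=tau2,
                              seed=np.random.default_rng(s_phi))
    if hotspot_areas:
        truth = implant_hotspot(truth, hotspot_areas, hotspot_multiplier)
    rates = ReferenceRates.from_per_100k(DEFAULT_RATES_PER_100K)
    records = simulate_registry_records(table, truth, decoy_fraction=decoy_fraction,
                                        seed=s_rec, rates=rates)
    table = tabulate_cases(records, table)
    return {"graph": graph, "table": table, "truth": truth,
            "records": records, "rates": rates}
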