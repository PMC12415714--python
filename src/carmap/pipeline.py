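"""End-to-end pipeline orchestration: standardize -> fit -> flag -> diagnose.

A :class:`PipelineConfig` (built directly, or loaded from YAML/JSON with
CLI-style overrides) names the inputs, output directory, model and chain
settings and decision thresholds.  :func:`run_pipeline` executes the stages,
writes the per-area risk summary (CSV and, when polygons are available,
GeoJSON), the posterior draws and a JSON manifest recording every default
the analysis leaves open — priors, neighbor definition, residual type,
quantile rule — so two runs can be compared by diffing manifests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .geography import AdjacencyGraph
from .model import LerouxCAR, McmcConfig, PosteriorDraws, PriorSpec
from .standardization import ReferenceRates, StratifiedAreaTable

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_adjacency", "load_draws"]


@dataclass
class PipelineConfig:
    counts_csv: str = ""
    adjacency: str = ""
    geojson: str | None = None
    rates_csv: str | None = None
    outdir: str = "carmap_out"
    # model
    beta_var: float = 1e5
    tau2_shape: float = 1.0
    tau2_scale: float = 0.01
    # chain
    n_burnin: int = 20000
    n_sample: int = 100000
    thin: int = 10
    n_chains: int = 1
    seed: int = 0
    # decisions
    thresholds: list[float] = field(default_factory=lambda: [1.25, 2.0])
    prob_threshold: float = 0.95
    moran_weighting: str = "row-standardized"
    write_draws: bool = True

    def __post_init__(self):
        if any(c <= 0 for c in self.thresholds):
            raise ValueError("thresholds must be positive")
        if not 0.0 < self.prob_threshold < 1.0:
            raise ValueError("prob_threshold must lie in (0, 1)")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(obj) - valid
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        obj.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**obj)

    def priors(self) -> PriorSpec:
        return PriorSpec(beta_var=self.beta_var, tau2_shape=self.tau2_shape,
                         tau2_scale=self.tau2_scale)

    def mcmc(self) -> McmcConfig:
        return McmcConfig(n_burnin=self.n_burnin, n_sample=self.n_sample,
                          thin=self.thin, seed=self.seed)


def load_adjacency(path) -> AdjacencyGraph:
    """Dispatch on extension: .gal, edge-list .csv, or GeoJSON (.geojson/.json)."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".gal":
        return AdjacencyGraph.from_gal(path)
    if ext == ".csv":
        return AdjacencyGraph.from_edge_csv(path)
    if ext in (".geojson", ".json"):
        return AdjacencyGraph.from_geojson(path)
    raise ValueError(f"unrecognised adjacency format: {path}")


def load_draws(outdir, graph_area_ids=None) -> PosteriorDraws:
    """Reload persisted posterior draws (scalars + phi CSVs + manifest)."""
    scalars = pd.read_csv(os.path.join(outdir, "draws_scalars.csv"))
    phi = pd.read_csv(os.path.join(outdir, "draws_phi.csv"))
    with open(os.path.join(outdir, "manifest.json")) as fh:
        manifest = json.load(fh)
    return PosteriorDraws(
        beta=scalars["beta"].to_numpy(), phi=phi.to_numpy(),
        tau2=scalars["tau2"].to_numpy(), rho=scalars["rho"].to_numpy(),
        area_ids=list(phi.columns), acceptance=manifest.get("acceptance", {}),
        config=McmcConfig(**manifest["mcmc"]),
        priors=PriorSpec(**manifest["priors"]))


def run_pipeline(config: PipelineConfig):
    """Execute standardize -> fit -> flag -> diagnose and write all outputs.

    Returns the fitted :class:`~carmap.model.LerouxCARResults`.  Stage
    failures raise with a stage-named message.
    """
    os.makedirs(config.outdir, exist_ok=True)
    warnings_log: list[str] = []

    def stage(name):
        logger.info("stage: %s", name)
        return name

    name = stage("standardize")
    try:
        table = StratifiedAreaTable.from_csv(config.counts_csv)
        graph = load_adjacency(config.adjacency) if config.adjacency else None
        if graph is None:
            raise ValueError("an adjacency source is required")
        rates = ReferenceRates.from_csv(config.rates_csv) if config.rates_csv else None
        model = LerouxCAR.from_table(table, graph, rates=rates, priors=config.priors())
        if model.dropped_areas_:
            warnings_log.append(
                f"dropped {len(model.dropped_areas_)} areas with zero expected counts")
        model.rates_.to_csv(os.path.join(config.outdir, "reference_rates.csv"))
    except Exception as exc:
        raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

    name = stage("fit")
    try:
        results = model.fit(config.mcmc(), n_chains=config.n_chains)
    except Exception as exc:
        raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

    name = stage("flag")
    try:
        summary = results.area_summary(thresholds=tuple(config.thresholds),
                                       prob_threshold=config.prob_threshold)
        summary.to_csv(os.path.join(config.outdir, "area_risk_summary.csv"), index=False)
        if config.geojson:
            from .postprocess import write_summary_geojson
            write_summary_geojson(summary, config.geojson,
                                  os.path.join(config.outdir, "area_risk_summary.geojson"))
    except Exception as exc:
        raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

    name = stage("diagnose")
    try:
        moran = results.moran_test(weighting=config.moran_weighting)
        conv = results.convergence() if results.draws.n_draws >= 200 else None
        diag = {"moran_i": moran.I, "moran_expected_null": moran.expected_null,
                "moran_z": moran.z, "moran_p": moran.p,
                "moran_weighting": moran.weighting}
        if conv is not None:
            diag["convergence"] = conv.reset_index().to_dict("records")
        with open(os.path.join(config.outdir, "diagnostics.json"), "w") as fh:
            json.dump(diag, fh, indent=1)
    except Exception as exc:
        raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

    results.save(config.outdir, write_draws=config.write_draws)
    manifest_path = os.path.join(config.outdir, "manifest.json")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    manifest["pipeline_config"] = dataclasses.asdict(config)
    manifest["warnings"] = warnings_log
    manifest["diagnostics"] = diag
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return results
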