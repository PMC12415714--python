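"""Bayesian spatial Poisson model with a Leroux CAR random effect.

The model for per-area observed counts O_i with standardized expected counts
E_i is

    O_i | phi  ~  Poisson(E_i * exp(beta + phi_i))
    phi        ~  N(0, tau2 * [rho*(D - W) + (1 - rho)*I]^{-1})
    beta       ~  N(0, V_beta)
    tau2       ~  InvGamma(a, b)
    rho        ~  Uniform[0, 1)

where W is the binary adjacency matrix, D the diagonal degree matrix.  The
Leroux precision interpolates between independent random effects (rho = 0)
and the intrinsic CAR (rho -> 1); its full conditional for a single phi_i is
Gaussian with

    mean = rho * sum_{j~i} phi_j / (rho*d_i + 1 - rho)
    var  = tau2 / (rho*d_i + 1 - rho).

Inference is Metropolis-within-Gibbs: adaptive univariate random-walk
Metropolis for each phi_i and for beta, an exact inverse-gamma Gibbs draw for
tau2, and random-walk Metropolis for rho using the spectral identity
log det[rho*(D-W) + (1-rho)*I] = sum_k log(rho*lambda_k + 1 - rho) with the
Laplacian eigenvalues lambda_k precomputed once per graph.

The module follows the Model/Results convention: build a :class:`LerouxCAR`
from data (or :meth:`LerouxCAR.from_table` from a stratified table), call
:meth:`~LerouxCAR.fit`, and read estimates, intervals, exceedance
probabilities and diagnostics off the returned :class:`LerouxCARResults`.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geography import AdjacencyGraph
from .standardization import (StratifiedAreaTable, ReferenceRates,
                              compute_reference_rates, expected_counts, raw_irr)

logger = logging.getLogger(__name__)

__all__ = ["PriorSpec", "McmcConfig", "ChainState", "PosteriorDraws",
           "phi_prior_conditional", "LerouxCAR", "LerouxCARResults", "run_chain"]


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters: beta ~ N(0, beta_var); tau2 ~ IG(tau2_shape, tau2_scale);
    rho ~ U[0, 1).  Defaults follow the reference CAR-fitting convention for
    this model class: a vague intercept, IG(1, 0.01) on the spatial variance."""

    beta_var: float = 1e5
    tau2_shape: float = 1.0
    tau2_scale: float = 0.01
    #: Exclusive upper bound of the uniform prior on rho.  The default keeps
    #: the full [0, 1) support; validation runs may bound it away from 1,
    #: where the Leroux covariance (and hence prior phi moments) diverges.
    rho_max: float = 1.0

    def __post_init__(self):
        if self.beta_var <= 0 or self.tau2_shape <= 0 or self.tau2_scale <= 0:
            raise ValueError("prior hyperparameters must be positive")
        if not 0.0 < self.rho_max <= 1.0:
            raise ValueError("rho_max must lie in (0, 1]")


@dataclass(frozen=True)
class McmcConfig:
    """Chain length, thinning and adaptation settings.

    Step sizes adapt by Robbins-Monro scaling toward ``adapt_target``
    acceptance until ``adapt_until`` (default: end of burn-in), then freeze
    so the sampling phase targets the exact stationary law.
    """

    n_burnin: int = 20000
    n_sample: int = 100000
    thin: int = 10
    seed: int = 0
    adapt_target: float = 0.4
    adapt_until: int | None = None

    def __post_init__(self):
        if self.n_burnin < 0 or self.n_sample < 1 or self.thin < 1:
            raise ValueError("invalid chain lengths")
        if not 0.0 < self.adapt_target < 1.0:
            raise ValueError("adapt_target must lie in (0, 1)")
        if self.adapt_until is not None and self.adapt_until > self.n_burnin:
            raise ValueError("adaptation must cease at or before end of burn-in")

    @property
    def effective_adapt_until(self) -> int:
        return self.n_burnin if self.adapt_until is None else self.adapt_until

    @property
    def n_draws(self) -> int:
        return self.n_sample // self.thin


@dataclass
class ChainState:
    beta: float
    phi: np.ndarray
    tau2: float
    rho: float
    step_beta: float = 0.1
    step_phi: float = 0.5
    step_rho: float = 0.1


@dataclass
class PosteriorDraws:
    """Retained MCMC draws plus bookkeeping."""

    beta: np.ndarray          # (n_draws,)
    phi: np.ndarray           # (n_draws, n_areas)
    tau2: np.ndarray          # (n_draws,)
    rho: np.ndarray           # (n_draws,)
    area_ids: list[str]
    acceptance: dict[str, float]
    config: McmcConfig
    priors: PriorSpec
    chain_id: int = 0

    @property
    def n_draws(self) -> int:
        return len(self.beta)

    @property
    def n_areas(self) -> int:
        return self.phi.shape[1]


def phi_prior_conditional(i: int, phi: np.ndarray, rho: float, tau2: float,
                          graph: AdjacencyGraph) -> tuple[float, float]:
    """Leroux full-conditional mean and variance of phi_i given the rest."""
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    d = graph.degrees[i]
    denom = rho * d + 1.0 - rho
    mean = rho * float(phi[graph.neighbors[i]].sum()) / denom
    return mean, tau2 / denom


class LerouxCAR:
    """Spatial Poisson intercept-plus-CAR model over an adjacency graph.

    Parameters
    ----------
    observed, expected
        Per-area counts O_i and standardized expected counts E_i (all E_i
        must be positive); ignored when ``likelihood=False`` (prior-only
        mode, used for sampler validation).
    graph
        The neighborhood structure.
    priors
        Hyperparameters; defaults to :class:`PriorSpec`.
    fixed
        Optional mapping holding any of ``beta``, ``tau2``, ``rho`` at fixed
        values (their updates are skipped).  When ``beta`` is fixed the phi
        recentring step is also skipped, because recentring moves mass
        between phi and the intercept.
    """

    def __init__(self, observed=None, expected=None, *, graph: AdjacencyGraph,
                 priors: PriorSpec | None = None,
                 fixed: Mapping[str, float] | None = None,
                 likelihood: bool = True, recentre: bool = True):
        self.graph = graph
        self.priors = priors or PriorSpec()
        self.fixed = dict(fixed or {})
        unknown = set(self.fixed) - {"beta", "tau2", "rho"}
        if unknown:
            raise ValueError(f"cannot fix parameters: {sorted(unknown)}")
        self.likelihood = likelihood
        # Recentring (subtract mean(phi), absorb into beta) stabilises the
        # weakly identified intercept-plus-proper-CAR decomposition, at the
        # price of a slight perturbation of the exact stationary law; exact-
        # kernel validation runs disable it.
        self.recentre = recentre
        if likelihood:
            observed = np.asarray(observed, dtype=float)
            expected = np.asarray(expected, dtype=float)
            if observed.shape != (graph.n,) or expected.shape != (graph.n,):
                raise ValueError("observed/expected must be vectors of length graph.n")
            if (expected <= 0).any():
                raise ValueError(
                    "all areas must have positive expected counts; drop E=0 areas first")
            if (observed < 0).any():
                raise ValueError("negative observed counts")
            self.observed = observed
            self.expected = expected
        else:
            self.observed = np.zeros(graph.n)
            self.expected = np.zeros(graph.n)
        # standardization context, populated by from_table
        self.rates_: ReferenceRates | None = None
        self.dropped_areas_: list[str] = []

    # ------------------------------------------------------------------ #

    @classmethod
    def from_table(cls, table: StratifiedAreaTable, graph: AdjacencyGraph,
                   rates: ReferenceRates | None = None,
                   priors: PriorSpec | None = None) -> "LerouxCAR":
        """Build the model from a stratified table by indirect standardization.

        Reference rates default to internal (computed from ``table``).  Areas
        with zero expected counts are dropped with a warning and the graph is
        restricted to the remaining areas.
        """
        if rates is None:
            rates = compute_reference_rates(table)
        e = expected_counts(table, rates)
        o = table.observed_by_area().reindex(e.index, fill_value=0)
        dropped = list(e.index[e <= 0])
        if dropped:
            logger.warning("dropping %d area(s) with zero expected counts", len(dropped))
            e = e[e > 0]
            o = o.reindex(e.index)
        missing = [a for a in e.index if a not in graph.index]
        if missing:
            raise ValueError(f"areas missing from graph: {missing[:5]}")
        sub = graph.subgraph(list(e.index)) if (dropped or len(e) != graph.n) else graph
        model = cls(o.to_numpy(), e.to_numpy(), graph=sub, priors=priors)
        model.rates_ = rates
        model.dropped_areas_ = dropped
        return model

    # ------------------------------------------------------------------ #
    # single-parameter updates (Metropolis-within-Gibbs kernel pieces)

    def update_phi_sweep(self, state: ChainState, rng: np.random.Generator) -> float:
        """One univariate random-walk Metropolis update per area, in index order.

        Returns the sweep acceptance fraction.  The log acceptance ratio
        combines the Poisson likelihood term O_i*phi_i - E_i*e^{beta+phi_i}
        with the Gaussian Leroux full conditional.  Recentring is applied
        separately by the chain driver.
        """
        n = self.graph.n
        phi = state.phi
        rho, tau2 = state.rho, state.tau2
        eb = math.exp(state.beta) if self.likelihood else 0.0
        neighbors = self.graph.neighbors
        degrees = self.graph.degrees
        O = self.observed
        E = self.expected
        eps = rng.standard_normal(n)
        logu = np.log(rng.random(n))
        step = state.step_phi
        accepted = 0
        use_lik = self.likelihood
        for i in range(n):
            d = degrees[i]
            denom = rho * d + 1.0 - rho
            pm = rho * float(phi[neighbors[i]].sum()) / denom if d else 0.0
            cur = phi[i]
            prop = cur + step * eps[i]
            delta = -((prop - pm) ** 2 - (cur - pm) ** 2) * denom / (2.0 * tau2)
            if use_lik:
                try:
                    delta += O[i] * (prop - cur) - E[i] * eb * (math.exp(prop) - math.exp(cur))
                except OverflowError:
                    delta = -math.inf
            if math.isnan(delta):
                raise RuntimeError(f"non-finite log-posterior in phi update at area {i}: "
                                   f"state={state}")
            if logu[i] < delta:
                phi[i] = prop
                accepted += 1
        return accepted / n

    def update_beta(self, state: ChainState, rng: np.random.Generator) -> bool:
        """Random-walk Metropolis on the intercept; returns acceptance."""
        vb = self.priors.beta_var
        cur = state.beta
        prop = cur + state.step_beta * rng.standard_normal()
        delta = -(prop * prop - cur * cur) / (2.0 * vb)
        if self.likelihood:
            s = float(np.dot(self.expected, np.exp(state.phi)))
            sum_o = float(self.observed.sum())
            try:
                delta += (prop - cur) * sum_o - s * (math.exp(prop) - math.exp(cur))
            except OverflowError:
                delta = -math.inf
        if math.isnan(delta):
            raise RuntimeError(f"non-finite log-posterior in beta update: state={state}")
        if math.log(rng.random()) < delta:
            state.beta = prop
            return True
        return False

    def _quad_form(self, phi: np.ndarray, rho: float) -> float:
        """phi' [rho*(D-W) + (1-rho)*I] phi via the edge-difference identity."""
        if self.graph.edges:
            ei, ej = self._edge_arrays()
            diff = phi[ei] - phi[ej]
            pairwise = float(diff @ diff)
        else:
            pairwise = 0.0
        return rho * pairwise + (1.0 - rho) * float(phi @ phi)

    def _edge_arrays(self):
        if not hasattr(self, "_ei"):
            self._ei = np.array([e[0] for e in self.graph.edges], dtype=np.intp)
            self._ej = np.array([e[1] for e in self.graph.edges], dtype=np.intp)
        return self._ei, self._ej

    def update_tau2(self, state: ChainState, rng: np.random.Generator) -> None:
        """Exact conjugate Gibbs draw: tau2 ~ IG(a + n/2, b + phi'R(rho)phi / 2)."""
        a = self.priors.tau2_shape + 0.5 * self.graph.n
        b = self.priors.tau2_scale + 0.5 * self._quad_form(state.phi, state.rho)
        state.tau2 = b / rng.gamma(a)

    def update_rho(self, state: ChainState, rng: np.random.Generator) -> bool:
        """Random-walk Metropolis on rho in [0, 1); proposals outside reject.

        log target(rho) = (1/2) sum_k log(rho*lambda_k + 1 - rho)
                          - phi'R(rho)phi / (2*tau2)
        using the precomputed Laplacian eigenvalues lambda_k.
        """
        cur = state.rho
        prop = cur + state.step_rho * rng.standard_normal()
        # consume the uniform regardless, to keep the draw stream aligned
        logu = math.log(rng.random())
        if not 0.0 <= prop < min(1.0, self.priors.rho_max):
            return False
        lam = self.graph.structure_eigenvalues()
        def logt(r):
            return (0.5 * float(np.log(r * lam + 1.0 - r).sum())
                    - self._quad_form(state.phi, r) / (2.0 * state.tau2))
        delta = logt(prop) - logt(cur)
        if math.isnan(delta):
            raise RuntimeError(f"non-finite log-posterior in rho update: state={state}")
        if logu < delta:
            state.rho = prop
            return True
        return False

    # ------------------------------------------------------------------ #

    def transition(self, state: ChainState, rng: np.random.Generator,
                   recentre: bool | None = None) -> ChainState:
        """One full Metropolis-within-Gibbs iteration, mutating ``state``.

        The exact composite kernel (``recentre=False``) leaves the posterior
        invariant; the default follows the model's ``recentre`` setting.
        """
        if recentre is None:
            recentre = self.recentre and self.likelihood and "beta" not in self.fixed
        self.update_phi_sweep(state, rng)
        if recentre:
            m = float(state.phi.mean())
            state.phi -= m
            state.beta += m
        if "beta" not in self.fixed:
            self.update_beta(state, rng)
        if "tau2" not in self.fixed:
            self.update_tau2(state, rng)
        if "rho" not in self.fixed:
            self.update_rho(state, rng)
        return state

    def _initial_state(self) -> ChainState:
        beta0 = 0.0
        if self.likelihood and "beta" not in self.fixed and self.observed.sum() > 0:
            beta0 = math.log(self.observed.sum() / self.expected.sum())
        return ChainState(
            beta=self.fixed.get("beta", beta0),
            phi=np.zeros(self.graph.n),
            tau2=self.fixed.get("tau2", 0.1),
            rho=self.fixed.get("rho", min(0.5, 0.5 * self.priors.rho_max)),
        )

    def run_chain(self, config: McmcConfig, chain_id: int = 0,
                  initial_state: ChainState | None = None) -> PosteriorDraws:
        """Run burn-in with adaptation then thinned sampling; deterministic per seed."""
        rng = np.random.default_rng(config.seed + chain_id)
        state = initial_state if initial_state is not None else self._initial_state()
        n_iter = config.n_burnin + config.n_sample
        adapt_until = config.effective_adapt_until
        target = config.adapt_target
        recentre = self.recentre and self.likelihood and "beta" not in self.fixed

        n_keep = config.n_draws
        out_beta = np.empty(n_keep)
        out_phi = np.empty((n_keep, self.graph.n))
        out_tau2 = np.empty(n_keep)
        out_rho = np.empty(n_keep)
        acc = {"phi": 0.0, "beta": 0, "rho": 0}
        n_acc_iters = 0
        k = 0
        for t in range(1, n_iter + 1):
            a_phi = self.update_phi_sweep(state, rng)
            if recentre:
                m = float(state.phi.mean())
                state.phi -= m
                state.beta += m
            a_beta = False
            if "beta" not in self.fixed:
                a_beta = self.update_beta(state, rng)
            if "tau2" not in self.fixed:
                self.update_tau2(state, rng)
            a_rho = False
            if "rho" not in self.fixed:
                a_rho = self.update_rho(state, rng)

            if t <= adapt_until:
                g = t ** -0.6
                state.step_phi = min(max(state.step_phi * math.exp(g * (a_phi - target)), 1e-3), 10.0)
                if "beta" not in self.fixed:
                    state.step_beta = min(max(state.step_beta * math.exp(g * (int(a_beta) - target)), 1e-4), 10.0)
                if "rho" not in self.fixed:
                    state.step_rho = min(max(state.step_rho * math.exp(g * (int(a_rho) - target)), 1e-4), 2.0)
            else:
                acc["phi"] += a_phi
                acc["beta"] += int(a_beta)
                acc["rho"] += int(a_rho)
                n_acc_iters += 1

            if t > config.n_burnin and (t - config.n_burnin) % config.thin == 0:
                out_beta[k] = state.beta
                out_phi[k] = state.phi
                out_tau2[k] = state.tau2
                out_rho[k] = state.rho
                k += 1
        rates = {key: (val / n_acc_iters if n_acc_iters else float("nan"))
                 for key, val in acc.items()}
        rates["step_phi"], rates["step_beta"], rates["step_rho"] = (
            state.step_phi, state.step_beta, state.step_rho)
        logger.info("chain %d done: acceptance phi=%.2f beta=%.2f rho=%.2f",
                    chain_id, rates["phi"], rates["beta"], rates["rho"])
        return PosteriorDraws(beta=out_beta[:k], phi=out_phi[:k], tau2=out_tau2[:k],
                              rho=out_rho[:k], area_ids=[str(a) for a in self.graph.area_ids],
                              acceptance=rates, config=config, priors=self.priors,
                              chain_id=chain_id)

    def fit(self, config: McmcConfig | None = None, n_chains: int = 1,
            **kwargs) -> "LerouxCARResults":
        """Fit by MCMC and return a results object.

        Keyword arguments override ``config`` fields (e.g. ``n_sample=5000``).
        With ``n_chains > 1``, chains are run at seed offsets and their
        retained draws concatenated.
        """
        if config is None:
            config = McmcConfig()
        if kwargs:
            config = McmcConfig(**{**asdict(config), **kwargs})
        chains = [self.run_chain(config, chain_id=c) for c in range(n_chains)]
        return LerouxCARResults(self, chains)


def run_chain(observed, expected, graph: AdjacencyGraph,
              priors: PriorSpec | None = None, config: McmcConfig | None = None,
              **model_kwargs) -> PosteriorDraws:
    """Functional entry point: build the model and run a single chain."""
    model = LerouxCAR(observed, expected, graph=graph, priors=priors, **model_kwargs)
    return model.run_chain(config or McmcConfig())


class LerouxCARResults:
    """Posterior summaries, exceedance flags and diagnostics of a fitted model."""

    def __init__(self, model: LerouxCAR, chains: Sequence[PosteriorDraws]):
        self.model = model
        self.chains = list(chains)
        d = chains[0]
        self.draws = PosteriorDraws(
            beta=np.concatenate([c.beta for c in chains]),
            phi=np.vstack([c.phi for c in chains]),
            tau2=np.concatenate([c.tau2 for c in chains]),
            rho=np.concatenate([c.rho for c in chains]),
            area_ids=d.area_ids, acceptance=d.acceptance,
            config=d.config, priors=d.priors)

    # -- posterior quantities ------------------------------------------ #

    def theta_draws(self) -> np.ndarray:
        """Smoothed IRR per draw and area: theta_i = exp(beta + phi_i)."""
        from .postprocess import irr_draws
        return irr_draws(self.draws)

    @property
    def smoothed_irr(self) -> pd.Series:
        """Posterior mean smoothed IRR per area."""
        return pd.Series(self.theta_draws().mean(axis=0), index=self.draws.area_ids,
                         name="post_mean_irr")

    def exceedance(self, c: float) -> pd.Series:
        from .postprocess import exceedance_probability
        p = exceedance_probability(self.theta_draws(), c)
        return pd.Series(p, index=self.draws.area_ids, name=f"p_gt_{c}")

    def area_summary(self, thresholds: Sequence[float] = (1.25, 2.0),
                     prob_threshold: float = 0.95) -> pd.DataFrame:
        from .postprocess import area_risk_summary
        return area_risk_summary(self.draws.area_ids, self.model.observed,
                                 self.model.expected, self.theta_draws(),
                                 thresholds=thresholds, prob_threshold=prob_threshold)

    # -- diagnostics --------------------------------------------------- #

    def pearson_residuals(self) -> pd.Series:
        from .diagnostics import pearson_residuals
        z = pearson_residuals(self.model.observed, self.model.expected,
                              self.smoothed_irr.to_numpy())
        return pd.Series(z, index=self.draws.area_ids, name="pearson_residual")

    def moran_test(self, weighting: str = "row-standardized"):
        """Moran's I of the Pearson residuals of the posterior-mean fit."""
        from .diagnostics import morans_i
        return morans_i(self.pearson_residuals().to_numpy(), self.model.graph,
                        weighting=weighting)

    def convergence(self) -> pd.DataFrame:
        from .diagnostics import convergence_summary
        return convergence_summary(self.draws)

    # -- presentation -------------------------------------------------- #

    def _param_table(self) -> pd.DataFrame:
        rows = []
        for name, x in [("beta", self.draws.beta), ("tau2", self.draws.tau2),
                        ("rho", self.draws.rho)]:
            lo, hi = np.quantile(x, [0.025, 0.975])
            rows.append({"param": name, "mean": x.mean(), "sd": x.std(ddof=1),
                         "q2.5": lo, "q97.5": hi})
        return pd.DataFrame(rows).set_index("param")

    def summary(self) -> str:
        """Human-readable fit summary (parameters, intervals, acceptance)."""
        tab = self._param_table()
        acc = self.draws.acceptance
        lines = ["Leroux CAR spatial Poisson model",
                 f"areas: {self.draws.n_areas}   retained draws: {self.draws.n_draws}"
                 f"   chains: {len(self.chains)}",
                 "",
                 tab.to_string(float_format=lambda v: f"{v: .4f}"),
                 "",
                 f"acceptance rates: phi={acc['phi']:.2f} beta={acc['beta']:.2f} "
                 f"rho={acc['rho']:.2f}"]
        fixed = self.model.fixed
        if fixed:
            lines.append(f"fixed parameters: {fixed}")
        return "\n".join(lines)

    def manifest(self) -> dict:
        """Run manifest: every modelling default the analysis leaves open."""
        from . import __version__
        return {
            "package": "carmap", "version": __version__,
            "model": "Poisson log-linear with Leroux CAR random effect",
            "smoothed_irr_definition": "exp(beta + phi_i)",
            "priors": asdict(self.draws.priors),
            "mcmc": asdict(self.draws.config),
            "n_chains": len(self.chains),
            "acceptance": self.draws.acceptance,
            "quantile_rule": "equal-tailed empirical, linear interpolation",
            "residual_type": "pearson",
            "moran_weighting_default": "row-standardized",
            "dropped_areas": self.model.dropped_areas_,
            "numpy_version": np.__version__,
        }

    def save(self, outdir, write_draws: bool = True) -> None:
        """Persist draws as columnar CSV (one file per block) plus a manifest."""
        import os
        os.makedirs(outdir, exist_ok=True)
        if write_draws:
            pd.DataFrame({"beta": self.draws.beta, "tau2": self.draws.tau2,
                          "rho": self.draws.rho}).to_csv(
                os.path.join(outdir, "draws_scalars.csv"), index=False)
            pd.DataFrame(self.draws.phi, columns=self.draws.area_ids).to_csv(
                os.path.join(outdir, "draws_phi.csv"), index=False)
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(self.manifest(), fh, indent=1)
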