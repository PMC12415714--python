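"""Model diagnostics: residual spatial autocorrelation, chain convergence,
and a brute-force quadrature oracle for validating the sampler.

Moran's I over a spatial weights graph measures whether the residuals of the
fitted model retain spatial structure the CAR effect failed to absorb; its
null expectation is -1/(n-1) and the analytic p-value uses the normal
approximation under the randomization assumption.  A permutation p-value is
available as a distribution-free alternative.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .geography import AdjacencyGraph

logger = logging.getLogger(__name__)

__all__ = ["MoranResult", "pearson_residuals", "morans_i",
           "morans_i_permutation_p", "convergence_summary",
           "grid_quadrature_oracle", "getting_it_right"]


@dataclass(frozen=True)
class MoranResult:
    """Moran's I with its randomization-null reference quantities."""

    I: float
    expected_null: float    # -1/(n-1)
    z: float
    p: float                # two-sided, normal approximation
    n: int
    S0: float               # sum of all weights
    weighting: str

    def __str__(self) -> str:  # pragma: no cover
        return (f"Moran's I = {self.I:.4f} (null {self.expected_null:.4f}), "
                f"z = {self.z:.3f}, two-sided p = {self.p:.3f} [{self.weighting}]")


def pearson_residuals(observed, expected, theta_hat) -> np.ndarray:
    """z_i = (O_i - mu_i)/sqrt(mu_i) with fitted means mu_i = E_i * theta_hat_i.

    Areas with mu_i = 0 are excluded with a warning (their residual is
    undefined); the returned vector keeps the remaining areas' order.
    """
    observed = np.asarray(observed, dtype=float)
    mu = np.asarray(expected, dtype=float) * np.asarray(theta_hat, dtype=float)
    keep = mu > 0
    if not keep.all():
        logger.warning("excluding %d area(s) with zero fitted mean from residuals",
                       int((~keep).sum()))
    return (observed[keep] - mu[keep]) / np.sqrt(mu[keep])


def _weight_matrix(graph: AdjacencyGraph, weighting: str) -> np.ndarray:
    W = graph.adjacency_matrix().toarray()
    if weighting in ("row-standardized", "row"):
        rs = W.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            W = np.where(rs > 0, W / rs, 0.0)
    elif weighting != "binary":
        raise ValueError("weighting must be 'binary' or 'row-standardized'")
    return W


def morans_i(z: np.ndarray, graph: AdjacencyGraph,
             weighting: str = "row-standardized") -> MoranResult:
    """Global Moran's I with analytic two-sided p under randomization.

        I = (n/S0) * sum_ij w_ij (z_i - zbar)(z_j - zbar) / sum_i (z_i - zbar)^2

    Requires n >= 3, a non-constant z, and a graph with at least one edge.
    The variance uses the randomization (permutation-moment) formula when
    n >= 4, falling back to the normality formula for n = 3.
    """
    z = np.asarray(z, dtype=float)
    n = len(z)
    if n < 3:
        raise ValueError("Moran's I needs at least 3 areas")
    if n != graph.n:
        raise ValueError("residual vector length must equal graph size")
    W = _weight_matrix(graph, weighting)
    S0 = float(W.sum())
    if S0 <= 0:
        raise ValueError("graph has no edges (S0 = 0); Moran's I undefined")
    zd = z - z.mean()
    denom = float(zd @ zd)
    if denom == 0:
        raise ValueError("residuals are constant; Moran's I undefined")
    num = float(zd @ W @ zd)
    I = (n / S0) * num / denom

    e_null = -1.0 / (n - 1)
    S1 = 0.5 * float(((W + W.T) ** 2).sum())
    S2 = float(((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum())
    if n >= 4:
        b2 = n * float((zd ** 4).sum()) / denom ** 2
        var = ((n * ((n * n - 3 * n + 3) * S1 - n * S2 + 3 * S0 * S0)
                - b2 * ((n * n - n) * S1 - 2 * n * S2 + 6 * S0 * S0))
               / ((n - 1) * (n - 2) * (n - 3) * S0 * S0)) - e_null ** 2
    else:
        var = ((n * n * S1 - n * S2 + 3 * S0 * S0)
               / (S0 * S0 * (n * n - 1))) - e_null ** 2
    var = max(var, 0.0)
    zscore = (I - e_null) / math.sqrt(var) if var > 0 else float("nan")
    p = 2.0 * scipy.stats.norm.sf(abs(zscore)) if var > 0 else float("nan")
    return MoranResult(I=I, expected_null=e_null, z=zscore, p=p, n=n, S0=S0,
                       weighting=weighting)


def morans_i_permutation_p(z: np.ndarray, graph: AdjacencyGraph,
                           n_perm: int = 999, seed: int = 0,
                           weighting: str = "row-standardized") -> float:
    """Two-sided permutation p-value for Moran's I.

    p = (1 + #{permutations with |I* - E| >= |I_obs - E|}) / (n_perm + 1),
    with both statistics centred at the null expectation E = -1/(n-1);
    deterministic given the seed.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    z = np.asarray(z, dtype=float)
    obs = morans_i(z, graph, weighting=weighting)
    W = _weight_matrix(graph, weighting)
    n, S0 = obs.n, obs.S0
    zd = z - z.mean()
    denom = float(zd @ zd)
    rng = np.random.default_rng(seed)
    count = 0
    ref = abs(obs.I - obs.expected_null)
    for _ in range(n_perm):
        perm = zd[rng.permutation(n)]
        i_star = (n / S0) * float(perm @ W @ perm) / denom
        if abs(i_star - obs.expected_null) >= ref - 1e-15:
            count += 1
    return (1 + count) / (n_perm + 1)


def _ess(x: np.ndarray) -> float:
    """Effective sample size by autocorrelation truncation.

    Sums sample autocorrelations until the first pair sum rho_{2k}+rho_{2k+1}
    turns negative (Geyer's initial positive sequence), then
    ESS = n / (1 + 2 * sum rho_k).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    xd = x - x.mean()
    v = float(xd @ xd) / n
    if v == 0:
        return float("nan")
    acf = np.correlate(xd, xd, mode="full")[n - 1:] / (n * v)
    s = 0.0
    k = 1
    while k + 1 < n:
        pair = acf[k] + acf[k + 1]
        if pair < 0:
            break
        s += pair
        k += 2
    return n / (1.0 + 2.0 * s)


def _geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z: compare means of the first 10% and last 50%,
    with each segment's variance inflated by its own autocorrelation (ESS)."""
    n = len(x)
    a = x[: max(int(first * n), 2)]
    b = x[-max(int(last * n), 2):]
    va = np.var(a, ddof=1) / max(_ess(a), 1.0)
    vb = np.var(b, ddof=1) / max(_ess(b), 1.0)
    if not np.isfinite(va + vb) or va + vb == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / math.sqrt(va + vb))


def convergence_summary(draws, include_phi: bool = False) -> pd.DataFrame:
    """Per-parameter ESS and Geweke z for the scalar chain parameters.

    ``draws`` is a :class:`~carmap.model.PosteriorDraws`-like object.  With
    ``include_phi=True`` every spatial effect is summarised too (slow for
    large graphs).  Requires at least 200 retained draws; constant chains
    yield NaN with a warning.
    """
    series = {"beta": np.asarray(draws.beta), "tau2": np.asarray(draws.tau2),
              "rho": np.asarray(draws.rho)}
    if include_phi:
        phi = np.asarray(draws.phi)
        for j in range(phi.shape[1]):
            series[f"phi[{j}]"] = phi[:, j]
    n = len(series["beta"])
    if n < 200:
        raise ValueError(f"need >= 200 retained draws for convergence summaries, got {n}")
    rows = []
    for name, x in series.items():
        if np.var(x) == 0:
            warnings.warn(f"chain for {name} is constant; diagnostics undefined")
            rows.append({"param": name, "ess": float("nan"), "geweke_z": float("nan")})
            continue
        rows.append({"param": name, "ess": _ess(x), "geweke_z": _geweke_z(x)})
    return pd.DataFrame(rows).set_index("param")


def getting_it_right(graph: AdjacencyGraph, expected, priors=None,
                     n_draws: int = 10000, steps_per_refresh: int = 6,
                     seed: int = 0) -> pd.DataFrame:
    """Sampler self-consistency check by prior-predictive simulation.

    Two routes to the joint prior-predictive distribution of
    (beta, phi, tau2, rho) must agree if the MCMC transition kernel has the
    correct stationary law:

    * marginal-conditional: draw the parameters directly from their priors;
    * successive-conditional: alternate a likelihood draw of the data with
      ``steps_per_refresh`` exact MCMC transitions given those data.

    First and second moments of rho, tau2 and phi_1 are compared by
    two-sample z-tests, with the successive chain's variance inflated by its
    autocorrelation time.  Requires priors with finite fourth moments: the
    default analysis priors (IG(1, .) on tau2, rho unbounded up to 1) make
    the tested moments infinite, so validation defaults to IG(6, 5),
    beta ~ N(0, 0.5) and rho ~ U[0, 0.95).  Returns a table of z-scores;
    recentring is disabled because only the exact kernel is being tested.
    """
    from .model import ChainState, LerouxCAR, PriorSpec
    from .synthetic import sample_leroux_gmrf

    if priors is None:
        priors = PriorSpec(beta_var=0.5, tau2_shape=6.0, tau2_scale=5.0, rho_max=0.95)
    expected = np.asarray(expected, dtype=float)
    rng = np.random.default_rng(seed)

    def prior_draw():
        rho = rng.random() * priors.rho_max
        tau2 = priors.tau2_scale / rng.gamma(priors.tau2_shape)
        beta = rng.normal(0.0, math.sqrt(priors.beta_var))
        phi = sample_leroux_gmrf(graph, rho, tau2, seed=rng)
        return beta, phi, tau2, rho

    mc = np.empty((n_draws, 3))
    for k in range(n_draws):
        _, phi, tau2, rho = prior_draw()
        mc[k] = (rho, tau2, phi[0])

    model = LerouxCAR(np.zeros(graph.n), expected, graph=graph, priors=priors,
                      recentre=False)
    beta, phi, tau2, rho = prior_draw()
    state = ChainState(beta=beta, phi=phi.copy(), tau2=tau2, rho=rho,
                       step_beta=0.4, step_phi=0.8, step_rho=0.2)
    sc = np.empty((n_draws, 3))
    for k in range(n_draws):
        mu = expected * np.exp(state.beta + state.phi)
        model.observed = rng.poisson(mu).astype(float)
        for _ in range(steps_per_refresh):
            model.transition(state, rng)
        sc[k] = (state.rho, state.tau2, state.phi[0])

    rows = []
    for j, name in enumerate(["rho", "tau2", "phi_1"]):
        for mom in (1, 2):
            x, y = mc[:, j] ** mom, sc[:, j] ** mom
            ess = max(_ess(y), 1.0)
            se = math.sqrt(np.var(x, ddof=1) / len(x) + np.var(y, ddof=1) / ess)
            rows.append({"param": name, "moment": mom,
                         "marginal_conditional": x.mean(),
                         "successive_conditional": y.mean(),
                         "z": (x.mean() - y.mean()) / se, "ess": ess})
    return pd.DataFrame(rows)


def grid_quadrature_oracle(observed, expected, graph: AdjacencyGraph,
                           rho: float, tau2: float, beta: float = 0.0,
                           half_width_sd: float = 6.0, n_points: int = 121,
                           refine_check: bool = True) -> pd.DataFrame:
    """Brute-force posterior moments of phi by dense grid quadrature (n <= 3).

    Evaluates Poisson likelihood times the Leroux Gaussian prior on a regular
    grid spanning ``half_width_sd`` prior standard deviations per dimension
    and normalises by Riemann summation.  Used as the independent oracle
    against which the MCMC sampler is validated.  Raises if halving the grid
    step moves any posterior mean by more than 1e-3 (grid too coarse).
    """
    from .geography import leroux_precision

    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    n = graph.n
    if n > 3:
        raise ValueError("grid quadrature oracle supports at most 3 areas")
    if observed.shape != (n,) or expected.shape != (n,):
        raise ValueError("observed/expected must match graph size")

    Q = leroux_precision(graph, rho, tau2)
    sd = np.sqrt(np.diag(np.linalg.inv(Q)))

    def moments(points_per_dim: int) -> tuple[np.ndarray, np.ndarray]:
        axes = [np.linspace(-half_width_sd * s, half_width_sd * s, points_per_dim)
                for s in sd]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)     # (G, n)
        logp = -0.5 * np.einsum("gi,ij,gj->g", pts, Q, pts)
        eta = beta + pts
        logp += (observed * eta - expected * np.exp(eta)).sum(axis=1)
        w = np.exp(logp - logp.max())
        w /= w.sum()
        mean = w @ pts
        var = w @ (pts - mean) ** 2
        return mean, var

    mean, var = moments(n_points)
    if refine_check:
        mean2, var2 = moments(2 * n_points - 1)
        if np.max(np.abs(mean2 - mean)) > 1e-3:
            raise RuntimeError("quadrature grid too coarse: refinement moved "
                               f"posterior means by {np.max(np.abs(mean2 - mean)):.2e}")
        mean, var = mean2, var2
    return pd.DataFrame({"post_mean_phi": mean, "post_var_phi": var},
                        index=[str(a) for a in graph.area_ids])
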