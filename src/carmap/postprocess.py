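"""From posterior draws to smoothed IRRs, exceedance probabilities and flags.

The headline output of the pipeline: for each area, the posterior mean of the
smoothed incidence rate ratio theta_i = exp(beta + phi_i), an equal-tailed
95% credible interval, and the posterior exceedance probabilities
p_i(c) = P(theta_i > c | data) at decision thresholds c (default 1.25 and
2.0, i.e. risk elevated by more than 25% or 100% over the national level).
An area is flagged when p_i(c) exceeds the probability cut (default 0.95);
both inequalities are strict.
"""

from __future__ import annotations

import json
import logging
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["irr_draws", "exceedance_probability", "flag_areas",
           "summarize_posterior", "area_risk_summary", "write_summary_geojson"]


def irr_draws(draws, include_intercept: bool = True) -> np.ndarray:
    """Per-draw, per-area smoothed IRR theta_i^(m) = exp(beta^(m) + phi_i^(m)).

    ``draws`` is any object with ``beta`` (m,) and ``phi`` (m, n) arrays.
    With ``include_intercept=False`` the alternative definition exp(phi_i)
    is returned (risk relative to the model's own baseline).
    """
    phi = np.asarray(draws.phi, dtype=float)
    if include_intercept:
        return np.exp(np.asarray(draws.beta, dtype=float)[:, None] + phi)
    return np.exp(phi)


def exceedance_probability(theta: np.ndarray, c: float) -> np.ndarray:
    """p_i(c) = fraction of draws with theta_i strictly above c."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if theta.shape[0] == 0:
        raise ValueError("no posterior draws")
    if theta.shape[0] < 100:
        logger.warning("exceedance probabilities from only %d draws", theta.shape[0])
    return (theta > c).mean(axis=0)


def flag_areas(p: np.ndarray, prob_threshold: float = 0.95) -> np.ndarray:
    """Boolean flags: p_i strictly greater than the probability threshold."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("exceedance probabilities must lie in [0, 1]")
    return p > prob_threshold


def summarize_posterior(theta: np.ndarray) -> pd.DataFrame:
    """Posterior mean and equal-tailed 95% credible interval per area.

    Quantiles are empirical with linear interpolation between order
    statistics (the numpy default), as recorded in the run manifest.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if theta.shape[0] < 100:
        logger.warning("posterior summaries from only %d draws", theta.shape[0])
    lo, hi = np.quantile(theta, [0.025, 0.975], axis=0)
    return pd.DataFrame({"post_mean_irr": theta.mean(axis=0), "ci_low": lo, "ci_high": hi})


def area_risk_summary(area_ids: Sequence[str], observed: np.ndarray,
                      expected: np.ndarray, theta: np.ndarray,
                      thresholds: Sequence[float] = (1.25, 2.0),
                      prob_threshold: float = 0.95) -> pd.DataFrame:
    """Full per-area risk table: counts, raw and smoothed IRR, p_i(c), flags."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    out = summarize_posterior(theta)
    out.insert(0, "area_id", list(area_ids))
    out.insert(1, "observed", observed)
    out.insert(2, "expected", expected)
    out.insert(3, "raw_irr", np.divide(observed, expected,
                                       out=np.full_like(observed, np.nan),
                                       where=expected > 0))
    for c in thresholds:
        p = exceedance_probability(theta, c)
        col = f"p_gt_{_fmt(c)}"
        out[col] = p
        out[f"flag_{_fmt(c)}"] = flag_areas(p, prob_threshold)
    return out


def _fmt(c: float) -> str:
    return f"{c:g}".replace(".", "_")


def write_summary_geojson(summary: pd.DataFrame, geojson_source, path,
                          id_property: str = "area_id") -> None:
    """Attach the risk summary to polygon features for choropleth rendering."""
    if isinstance(geojson_source, (str, bytes)):
        with open(geojson_source) as fh:
            obj = json.load(fh)
    else:
        obj = geojson_source
    rows = {str(r["area_id"]): r for r in summary.to_dict("records")}
    feats = []
    for feat in obj.get("features", []):
        ident = str((feat.get("properties") or {}).get(id_property))
        if ident in rows:
            props = dict(feat.get("properties") or {})
            props.update({k: (bool(v) if isinstance(v, (bool, np.bool_)) else v)
                          for k, v in rows[ident].items()})
            feats.append({**feat, "properties": props})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
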