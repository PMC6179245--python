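"""Residual spatial-autocorrelation diagnostics.

After fitting, each station gets a site-level residual: naive use (1 if
the species was ever detected there, else 0) minus the posterior mean
site-use probability.  A distance-binned correlogram of those residuals,
with a station-bootstrap band, shows whether spatial structure remains.
Comparing the correlogram from a fit without the area random intercept
(a plain logit model, tau = 0) against the hierarchical fit shows how
much of the spatial autocorrelation the grouping intercept absorbs.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .covariates import CovariateTable
from .model import McmcSettings, ModelConfig, PosteriorDraws, run_mcmc
from .records_io import DetectionHistory, StationInfo

__all__ = ["site_residuals", "fit_for_residuals", "distance_correlogram"]

RESIDUAL_KINDS = ("naive_glm", "random_intercept")


def site_residuals(history: DetectionHistory,
                   stations: Sequence[StationInfo],
                   psi: np.ndarray | PosteriorDraws) -> pd.DataFrame:
    """Observed-vs-expected site-use residuals, one per station.

    ``residual_i = naive_use_i - psi_i`` where ``psi`` is the posterior
    mean site-use probability per station (an array aligned with
    ``history.sites``, or a :class:`PosteriorDraws` from which it is
    taken).
    """
    if isinstance(psi, PosteriorDraws):
        if psi.sites != list(history.sites):
            raise ValueError("fit and history cover different station sets")
        psi = psi.psi_mean
    psi = np.asarray(psi, dtype=float)
    if psi.shape != (len(history.sites),):
        raise ValueError("psi must have one value per history site")
    by_id = {s.station_id: s for s in stations}
    missing = [sid for sid in history.sites if sid not in by_id]
    if missing:
        raise ValueError(f"stations missing from station table: {missing}")
    naive = history.naive_use()
    return pd.DataFrame({
        "station_id": history.sites,
        "x": [by_id[s].x for s in history.sites],
        "y": [by_id[s].y for s in history.sites],
        "residual": naive - psi,
    })


def fit_for_residuals(history: DetectionHistory,
                      covariates: CovariateTable,
                      stations: Sequence[StationInfo],
                      kind: str = "random_intercept",
                      config: ModelConfig | None = None,
                      settings: McmcSettings | None = None) -> pd.DataFrame:
    """Fit the model in one of two variants and return its residual set.

    ``kind="random_intercept"`` is the full hierarchical model;
    ``kind="naive_glm"`` disables the area random intercept (tau fixed at
    0, single shared intercept), mimicking an unstructured logit fit.
    """
    if kind not in RESIDUAL_KINDS:
        raise ValueError(f"kind must be one of {RESIDUAL_KINDS}")
    config = config or ModelConfig()
    if kind == "naive_glm":
        from dataclasses import replace

        config = replace(config, tau_fixed=0.0)
    draws = run_mcmc(history, covariates, stations, config, settings)
    return site_residuals(history, stations, draws)


def _bin_correlations(res: np.ndarray, dist: np.ndarray, edges: np.ndarray,
                      min_pairs: int) -> tuple[np.ndarray, np.ndarray]:
    """Within-bin Pearson correlation of residual pairs.

    Each unordered pair enters in both orders, making the estimator
    symmetric; bins with fewer than ``min_pairs`` pairs are NaN.
    """
    n = len(res)
    iu, ju = np.triu_indices(n, k=1)
    d = dist[iu, ju]
    corr = np.full(len(edges) - 1, np.nan)
    npairs = np.zeros(len(edges) - 1, dtype=int)
    for b in range(len(edges) - 1):
        sel = (d >= edges[b]) & (d < edges[b + 1])
        npairs[b] = int(sel.sum())
        if npairs[b] < min_pairs:
            continue
        u = np.concatenate([res[iu[sel]], res[ju[sel]]])
        v = np.concatenate([res[ju[sel]], res[iu[sel]]])
        su, sv = u.std(), v.std()
        if su == 0 or sv == 0:
            continue
        corr[b] = float(np.corrcoef(u, v)[0, 1])
    return corr, npairs


def distance_correlogram(residuals: pd.DataFrame,
                         n_bins: int = 10,
                         max_distance_km: float | None = None,
                         n_boot: int = 200,
                         min_pairs: int = 5,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Distance-binned nonparametric correlogram with a bootstrap band.

    Bins are equal-width up to ``max_distance_km`` (default: half the
    maximum pairwise distance).  The 95% band comes from ``n_boot``
    bootstrap resamples of stations; resampled pairs that reuse the same
    original station are dropped.  Returns columns bin_mid_km,
    correlation, lower, upper, n_pairs.
    """
    if len(residuals) < 2:
        raise ValueError("need at least two stations")
    rng = np.random.default_rng(0) if rng is None else rng
    xy = residuals[["x", "y"]].to_numpy(dtype=float)
    res = residuals["residual"].to_numpy(dtype=float)
    dist = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)) / 1000.0  # km
    dmax = max_distance_km or float(dist.max() / 2.0)
    edges = np.linspace(0.0, dmax, n_bins + 1)

    corr, npairs = _bin_correlations(res, dist, edges, min_pairs)

    boot = np.full((n_boot, n_bins), np.nan)
    n = len(res)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        # pair distances follow the resampled stations; identical-origin
        # pairs (distance 0 with identical residuals) are excluded
        order = idx
        sub_d = dist[np.ix_(order, order)]
        sub_r = res[order]
        same = order[:, None] == order[None, :]
        sub_d = np.where(same, np.nan, sub_d)
        boot[b] = _masked_bin_corr(sub_r, sub_d, edges, min_pairs)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        lower = np.nanpercentile(boot, 2.5, axis=0)
        upper = np.nanpercentile(boot, 97.5, axis=0)
    mids = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({
        "bin_mid_km": mids,
        "correlation": corr,
        "lower": lower,
        "upper": upper,
        "n_pairs": npairs,
    })


def _masked_bin_corr(res, dist, edges, min_pairs):
    n = len(res)
    iu, ju = np.triu_indices(n, k=1)
    d = dist[iu, ju]
    ok = ~np.isnan(d)
    iu, ju, d = iu[ok], ju[ok], d[ok]
    out = np.full(len(edges) - 1, np.nan)
    for b in range(len(edges) - 1):
        sel = (d >= edges[b]) & (d < edges[b + 1])
        if sel.sum() < min_pairs:
            continue
        u = np.concatenate([res[iu[sel]], res[ju[sel]]])
        v = np.concatenate([res[ju[sel]], res[iu[sel]]])
        if u.std() == 0 or v.std() == 0:
            continue
        out[b] = np.corrcoef(u, v)[0, 1]
    return out
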