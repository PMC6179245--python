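"""Hierarchical Bayesian site-use model with indicator variable selection.

The model is a single-season occupancy model on the logit scale.  Site i
in sampling area a is used with probability

    logit(psi_i) = alpha_area(a) + sum_c w_c * alpha_c * x_ic,

where ``alpha_area ~ Normal(mu, tau^2)`` is an area-level random
intercept and ``w_c ~ Bernoulli(0.5)`` are Kuo-Mallick inclusion
indicators switching each covariate in or out of the model.  Given use
(Z_i = 1), detection in occasion j follows

    logit(p_ij) = beta0 + beta_k * Trail_i,

with the animal-trail category as reference.  Slopes and detection
coefficients carry uniform priors on a wide logit-scale box (default
(-10, 10)); ``mu ~ Normal(0, 10^2)`` and ``tau ~ Uniform(0, 10)`` on the
SD scale.  The posterior is sampled by Metropolis-within-Gibbs (see
``siteuse._mcmc``); posterior means of the indicators are the covariates'
inclusion probabilities and averaging ``w_c * alpha_c`` over the draws
gives model-averaged coefficients across the 2^C candidate models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _mcmc
from .covariates import CovariateTable
from .records_io import DetectionHistory, StationInfo, TRAIL_TYPES

__all__ = [
    "ModelConfig",
    "McmcSettings",
    "PosteriorDraws",
    "site_marginal_loglik",
    "update_latent_z",
    "run_mcmc",
    "compute_rhat",
    "summarize",
    "model_average_coefficients",
    "estimate_sites_used",
    "predict_site_use_curve",
]


@dataclass(frozen=True)
class ModelConfig:
    """Priors and model-structure switches.

    ``mu_fixed`` / ``tau_fixed`` pin the hyperparameters (``tau_fixed=0``
    disables the random intercept entirely, leaving a single shared
    occupancy intercept ``mu``).
    """

    coef_low: float = -10.0
    coef_high: float = 10.0
    mu_loc: float = 0.0
    mu_scale: float = 10.0
    tau_max: float = 10.0
    inclusion_prior: float = 0.5
    inclusion_prior_detection: float = 0.5
    select_occupancy: bool = True
    select_detection: bool = True
    reference_trail: str = "AT"
    mu_fixed: float | None = None
    tau_fixed: float | None = None

    def __post_init__(self) -> None:
        if not self.coef_low < self.coef_high:
            raise ValueError("coef_low must be < coef_high")
        if not 0.0 < self.inclusion_prior < 1.0:
            raise ValueError("inclusion_prior must be in (0, 1)")
        if not 0.0 < self.inclusion_prior_detection < 1.0:
            raise ValueError("inclusion_prior_detection must be in (0, 1)")


@dataclass(frozen=True)
class McmcSettings:
    """Chain geometry.  Defaults match the headline fit: three chains of
    500 000 iterations, 50 000 burn-in, thinned by 10."""

    chains: int = 3
    iterations: int = 500_000
    burn_in: int = 50_000
    thin: int = 10
    seed: int = 1

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.chains < 1:
            raise ValueError("need at least one chain")

    @classmethod
    def reduced(cls, seed: int = 1, chains: int = 3) -> "McmcSettings":
        """Short test-scale chains (3 x 20 000, 4 000 burn-in, thin 5)."""
        return cls(chains=chains, iterations=20_000, burn_in=4_000, thin=5, seed=seed)


def site_marginal_loglik(psi: float, p_vec, y_vec) -> float:
    """Log marginal likelihood of one site's detection history.

    Marginalizes the latent use state:
    ``log[ psi * prod_j p_j^y_j (1-p_j)^(1-y_j) + (1-psi) * 1{all y = 0} ]``.
    ``y_vec`` must contain only observed occasions (missing cells dropped).
    Returns ``-inf`` (not an exception) for impossible data such as a
    detection with ``p = 0`` and ``psi`` giving no support.
    """
    p = np.asarray(p_vec, dtype=float)
    y = np.asarray(y_vec, dtype=float)
    if not 0.0 <= psi <= 1.0 or np.any(p < 0) or np.any(p > 1):
        raise ValueError("psi and p must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        ll_det = np.sum(np.where(y == 1, np.log(p), np.log1p(-p)))
    term_used = psi * np.exp(ll_det) if np.isfinite(ll_det) else 0.0
    term_unused = (1.0 - psi) if np.all(y == 0) else 0.0
    total = term_used + term_unused
    return float(np.log(total)) if total > 0 else -np.inf


def update_latent_z(psi, p, y, rng: np.random.Generator | None = None):
    """Sample the latent use indicators Z given parameters and data.

    ``psi`` is (n,); ``p`` and ``y`` are (n, J) with NaN in ``y`` marking
    missing occasions.  Sites with at least one detection have Z = 1 with
    probability one; for all-zero sites
    ``P(Z=1) = psi*q / (psi*q + 1 - psi)`` with ``q = prod_j (1 - p_ij)``
    over observed occasions.  Returns ``(z, prob)``.
    """
    psi = np.atleast_1d(np.asarray(psi, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    obs = ~np.isnan(y)
    detected = np.nansum(y, axis=1) > 0
    with np.errstate(divide="ignore"):  # p = 1 gives q = 0, a valid limit
        logq = np.where(obs, np.log1p(-np.where(obs, p, 0.0)), 0.0).sum(axis=1)
    q = np.exp(logq)
    prob = np.where(detected, 1.0, psi * q / (psi * q + 1.0 - psi))
    rng = np.random.default_rng() if rng is None else rng
    z = (rng.random(prob.shape) < prob).astype(int)
    z[detected] = 1
    return z, prob


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, kept per chain for convergence diagnostics."""

    array: np.ndarray                     # (chains, n_kept, P)
    names: list[str]
    sites: list[str]
    covariate_names: list[str]
    area_labels: list[str]
    trail_labels: list[str]               # non-reference levels, model order
    psi_mean: np.ndarray                  # (n_sites,) posterior mean site-use prob
    z_mean: np.ndarray                    # (n_sites,) posterior mean of Z
    config: ModelConfig
    settings: McmcSettings

    def __post_init__(self) -> None:
        self._index = {name: k for k, name in enumerate(self.names)}

    @property
    def n_draws(self) -> int:
        return self.array.shape[0] * self.array.shape[1]

    def get(self, name: str, pooled: bool = False) -> np.ndarray:
        """Draws of one parameter, shape (chains, n_kept) or flat."""
        arr = self.array[:, :, self._index[name]]
        return arr.reshape(-1) if pooled else arr

    def to_frame(self) -> pd.DataFrame:
        """Long table: chain, draw, parameter, value."""
        ch, nd, P = self.array.shape
        rows = {
            "chain": np.repeat(np.arange(ch), nd * P),
            "draw": np.tile(np.repeat(np.arange(nd), P), ch),
            "parameter": np.tile(self.names, ch * nd),
            "value": self.array.reshape(-1),
        }
        return pd.DataFrame(rows)


def _display_names(draws: PosteriorDraws) -> dict[str, str]:
    out = {}
    for a, lbl in enumerate(draws.area_labels):
        out[f"alpha_area[{a}]"] = f"alpha_area[{lbl}]"
    for c, nm in enumerate(draws.covariate_names):
        out[f"alpha[{c}]"] = f"alpha[{nm}]"
        out[f"w[{c}]"] = f"w[{nm}]"
    for t, nm in enumerate(draws.trail_labels):
        out[f"beta[{t}]"] = f"beta[{nm}]"
        out[f"w_beta[{t}]"] = f"w_beta[{nm}]"
    return out


def run_mcmc(history: DetectionHistory,
             covariates: CovariateTable,
             stations: Sequence[StationInfo],
             config: ModelConfig | None = None,
             settings: McmcSettings | None = None) -> PosteriorDraws:
    """Fit the site-use model by MCMC and return the retained draws.

    ``covariates`` must be standardized; every sampling area must contain
    at least one station.  One master seed fans out deterministic
    per-chain seeds.
    """
    config = config or ModelConfig()
    settings = settings or McmcSettings()
    if not covariates.standardized:
        raise ValueError("covariates must be z-score standardized before fitting")

    by_id = {s.station_id: s for s in stations}
    missing = [sid for sid in history.sites if sid not in by_id]
    if missing:
        raise ValueError(f"stations missing from station table: {missing}")
    sts = [by_id[sid] for sid in history.sites]

    area_labels = sorted({s.area for s in stations})
    area_idx = np.array([area_labels.index(s.area) for s in sts], dtype=np.int64)
    counts = np.bincount(area_idx, minlength=len(area_labels))
    if (counts == 0).any():
        empty = [area_labels[a] for a in np.flatnonzero(counts == 0)]
        raise ValueError(f"sampling area(s) with no surveyed stations: {empty}")

    ref = config.reference_trail
    trails_present = sorted({s.trail_type for s in sts})
    if ref in trails_present:
        trail_levels = [ref] + [t for t in trails_present if t != ref]
    else:
        trail_levels = trails_present
    trail_idx = np.array([trail_levels.index(s.trail_type) for s in sts], dtype=np.int64)

    x = covariates.data.reindex(history.sites).to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("covariate table does not cover all history sites")

    obs = ~np.isnan(history.y)
    m = obs.sum(axis=1).astype(float)
    d = np.nansum(history.y, axis=1)
    det = (d > 0).astype(np.int64)

    n_areas, n_trail, C = len(area_labels), len(trail_levels), x.shape[1]
    seeds = np.random.SeedSequence(settings.seed).generate_state(settings.chains) % (2**31)

    chains, psis, zs = [], [], []
    for s in seeds:
        out, psi_mean, z_mean = _mcmc.run_chain(
            np.int64(s), settings.iterations, settings.burn_in, settings.thin,
            np.ascontiguousarray(x), area_idx, trail_idx, n_areas, n_trail,
            m, d, det,
            config.coef_low, config.coef_high, config.mu_loc, config.mu_scale,
            config.tau_max, config.inclusion_prior, config.inclusion_prior_detection,
            config.select_occupancy, config.select_detection,
            config.mu_fixed is not None, float(config.mu_fixed or 0.0),
            config.tau_fixed is not None, float(config.tau_fixed or 0.0),
        )
        chains.append(out)
        psis.append(psi_mean)
        zs.append(z_mean)

    raw_names = _mcmc.param_layout(n_areas, C, n_trail - 1)
    draws = PosteriorDraws(
        array=np.stack(chains),
        names=raw_names,
        sites=list(history.sites),
        covariate_names=list(covariates.columns),
        area_labels=area_labels,
        trail_labels=trail_levels[1:],
        psi_mean=np.mean(psis, axis=0),
        z_mean=np.mean(zs, axis=0),
        config=config,
        settings=settings,
    )
    display = _display_names(draws)
    draws.names = [display.get(n, n) for n in raw_names]
    draws.__post_init__()
    return draws


def compute_rhat(chains) -> float:
    """Classic split-chain Gelman-Rubin potential scale reduction factor.

    ``chains`` is (m, n): m >= 2 chains of n >= 10 retained draws each.
    Each chain is split in half; R-hat is ``sqrt(var_hat / W)`` with
    ``var_hat = (n-1)/n * W + B/n``.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two chains of draws")
    if x.shape[1] < 10:
        raise ValueError("need at least 10 retained draws per chain")
    half = x.shape[1] // 2
    splits = np.concatenate([x[:, :half], x[:, half: 2 * half]], axis=0)
    n = splits.shape[1]
    chain_means = splits.mean(axis=1)
    B = n * np.var(chain_means, ddof=1)
    W = np.mean(np.var(splits, axis=1, ddof=1))
    if W == 0:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def _q(a, lo=2.5, hi=97.5):
    return np.percentile(a, lo), np.percentile(a, hi)


def summarize(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior summary: mean, SD, 95% CI, R-hat per parameter, with the
    inclusion probability alongside each selectable coefficient."""
    rows = []
    wc = {f"alpha[{c}]": f"w[{c}]" for c in draws.covariate_names}
    wc.update({f"beta[{t}]": f"w_beta[{t}]" for t in draws.trail_labels})
    for name in draws.names:
        ch = draws.get(name)
        flat = ch.reshape(-1)
        lo, hi = _q(flat)
        row = {
            "parameter": name,
            "mean": flat.mean(),
            "sd": flat.std(ddof=1),
            "ci_low": lo,
            "ci_high": hi,
            "rhat": compute_rhat(ch),
        }
        if name in wc:
            row["w"] = draws.get(wc[name], pooled=True).mean()
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")


def model_average_coefficients(draws: PosteriorDraws) -> pd.DataFrame:
    """Model-averaged coefficients across the visited model space.

    For each selectable coefficient: the posterior inclusion probability
    ``w`` (mean of the indicator), the model-averaged coefficient
    (posterior mean of ``w * coef``, zero when excluded), and the
    conditional-on-inclusion mean.  The conditional mean is NaN, with
    ``conditional_defined`` False, if the indicator was never on.
    """
    pairs = [(f"alpha[{c}]", f"w[{c}]") for c in draws.covariate_names]
    pairs += [(f"beta[{t}]", f"w_beta[{t}]") for t in draws.trail_labels]
    rows = []
    for coef_name, w_name in pairs:
        a = draws.get(coef_name, pooled=True)
        w = draws.get(w_name, pooled=True)
        wa = w * a
        inc = w == 1
        lo, hi = _q(wa)
        rows.append({
            "parameter": coef_name,
            "w": w.mean(),
            "mean_model_avg": wa.mean(),
            "sd_model_avg": wa.std(ddof=1),
            "ci_low_model_avg": lo,
            "ci_high_model_avg": hi,
            "mean_conditional": a[inc].mean() if inc.any() else np.nan,
            "sd_conditional": a[inc].std(ddof=1) if inc.sum() > 1 else np.nan,
            "conditional_defined": bool(inc.any()),
        })
    return pd.DataFrame(rows).set_index("parameter")


def estimate_sites_used(draws: PosteriorDraws) -> dict:
    """Posterior of the number of used sites, sum_i Z_i per draw."""
    ns = draws.get("n_sites_used", pooled=True)
    lo, hi = _q(ns)
    return {"mean": float(ns.mean()), "sd": float(ns.std(ddof=1)),
            "ci_low": float(lo), "ci_high": float(hi),
            "min": float(ns.min()), "max": float(ns.max())}


def predict_site_use_curve(draws: PosteriorDraws, covariate_name: str,
                           grid=None, n_curve_draws: int = 200,
                           rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Predicted site-use curve along one standardized covariate.

    ``psi(z) = inverse-logit(mu + (w_c * alpha_c) * z)`` with the other
    covariates held at their mean (0 on the z scale).  The mean curve
    uses all draws; the pointwise band comes from a random posterior
    subsample (default 200 draws).
    """
    if covariate_name not in draws.covariate_names:
        raise KeyError(f"unknown covariate {covariate_name!r}; "
                       f"have {draws.covariate_names}")
    rng = np.random.default_rng(0) if rng is None else rng
    grid = np.linspace(-2.5, 2.5, 41) if grid is None else np.asarray(grid, dtype=float)
    mu = draws.get("mu", pooled=True)
    wa = (draws.get(f"w[{covariate_name}]", pooled=True)
          * draws.get(f"alpha[{covariate_name}]", pooled=True))
    eta = mu[:, None] + wa[:, None] * grid[None, :]
    psi = 1.0 / (1.0 + np.exp(-eta))
    k = min(n_curve_draws, psi.shape[0])
    sub = psi[rng.choice(psi.shape[0], size=k, replace=False)]
    return pd.DataFrame({
        "z": grid,
        "psi_mean": psi.mean(axis=0),
        "psi_lower": np.percentile(sub, 2.5, axis=0),
        "psi_upper": np.percentile(sub, 97.5, axis=0),
    })
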