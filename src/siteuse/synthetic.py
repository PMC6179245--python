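"""Synthetic camera-trap landscapes with known truth.

Generates surveys with the statistical structure the site-use analysis
assumes, at the design scale of the study it emulates: 127 stations in
11 clustered sampling areas spread across a protection gradient
(national park / wildlife management area / village land, 77/16/35
stations), ~32 weekly occasions with ragged per-area effort, Bernoulli
site use on the logit scale driven by four standardized covariates plus
an area-level random intercept, and detection driven by a three-level
trail-type factor.

The generator draws covariates with the gradients the real landscape
shows - livestock concentrated in village lands, prey biomass (CPUE)
highest inside the park, households clustered around villages - and then
simulates use and detection from the same model the sampler fits, so
parameter-recovery tests have an exact known truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .covariates import COVARIATE_COLUMNS, CovariateTable, zscore_standardize
from .model import PosteriorDraws, model_average_coefficients
from .records_io import (DetectionHistory, DetectionRecord, OccasionGrid,
                         StationInfo, compute_effort)

__all__ = [
    "AREA_LAYOUT",
    "SyntheticTruth",
    "GradientParams",
    "simulate_stations",
    "simulate_covariates",
    "simulate_detection_data",
    "evaluate_recovery",
]

# (area, zone, n stations, mean active days per station) - the default
# design mirrors the 11-area layout (77 park / 16 WMA / 34 village land
# stations, 127 total) with one long-running area and several short
# windows.
AREA_LAYOUT = [
    ("Mdonya", "national_park", 9, 25),
    ("Kwihala", "national_park", 9, 22),
    ("Msembe", "national_park", 42, 177),
    ("Mwagusi", "national_park", 9, 19),
    ("Lunda-Ilolo", "national_park", 8, 25),
    ("Pawaga", "wma", 8, 92),
    ("Lunda", "wma", 8, 108),
    ("Idodi", "village_land", 9, 75),
    ("Malinzanga", "village_land", 9, 80),
    ("Nyamahana", "village_land", 8, 118),
    ("Magosi", "village_land", 8, 82),
]

# west -> east protection gradient, metres
_ZONE_XBAND = {
    "national_park": (0.0, 45_000.0),
    "wma": (50_000.0, 62_000.0),
    "village_land": (67_000.0, 90_000.0),
}
_YBAND = (0.0, 45_000.0)


@dataclass
class SyntheticTruth:
    """The generating parameter set, stored with every dataset.

    ``alpha`` is ordered as the covariate columns (livestock, dist_river,
    dist_household, cpue); ``beta_k`` are the NT and RD trail contrasts
    against the animal-trail reference.
    """

    mu: float = -0.75
    tau: float = 1.0
    alpha: tuple = (-2.0, 0.0, 2.0, 0.0)
    beta0: float = -1.6
    beta_k: tuple = (0.0, 0.0)
    area_effects: dict | None = None
    seed: int | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["alpha"] = tuple(d["alpha"])
        d["beta_k"] = tuple(d["beta_k"])
        return cls(**d)


@dataclass
class GradientParams:
    """Covariate-gradient configuration.

    ``strength`` in [0, 1] scales the zone contrasts; at 0 every
    covariate is drawn iid from a common marginal, so covariates are
    exchangeable across zones (the null configuration).
    """

    strength: float = 1.0
    livestock_mean: dict = field(default_factory=lambda: {
        "national_park": 0.05, "wma": 1.5, "village_land": 80.0})
    livestock_dispersion: float = 0.5
    cpue_median: dict = field(default_factory=lambda: {
        "national_park": 3000.0, "wma": 1500.0, "village_land": 300.0})
    cpue_sigma: float = 0.8
    households_per_area: dict = field(default_factory=lambda: {
        "national_park": 0, "wma": 5, "village_land": 30})
    household_spread: float = 4000.0


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_stations(n_areas: int = 11,
                      stations_per_area=None,
                      min_spacing: float = 1_500.0,
                      area_spacing: float = 15_000.0,
                      layout=None,
                      seed=0,
                      area_half_width: float | None = None,
                      max_tries: int = 2_000) -> list[StationInfo]:
    """Place clustered stations respecting the survey spacing rules.

    Stations within an area are at least ``min_spacing`` apart and area
    centroids at least ``area_spacing`` apart (rejection sampling; raises
    after ``max_tries`` failed placements, suggesting a larger extent).
    ``layout`` defaults to :data:`AREA_LAYOUT` truncated/overridden by
    ``n_areas`` and ``stations_per_area``.
    """
    rng = _rng(seed)
    if layout is None:
        layout = [row[:3] for row in AREA_LAYOUT[:n_areas]]
        if stations_per_area is not None:
            layout = [(a, z, int(stations_per_area)) for a, z, _ in layout]
    centroids: list[tuple[float, float]] = []
    placed: list[tuple[str, str, float, float]] = []
    for name, zone, n_st in layout:
        x0, x1 = _ZONE_XBAND[zone]
        for attempt in range(max_tries + 1):
            cx = rng.uniform(x0, x1)
            cy = rng.uniform(*_YBAND)
            if all(np.hypot(cx - px, cy - py) >= area_spacing for px, py in centroids):
                break
        else:
            raise RuntimeError(
                f"could not place area {name} {area_spacing / 1000:.0f} km from "
                "the others; enlarge the zone extents or reduce area_spacing")
        centroids.append((cx, cy))
        # default extent scales with the number of stations so the default
        # design always packs; a fixed half-width can make packing infeasible
        half = area_half_width or max(3_000.0, 0.9 * min_spacing * np.sqrt(n_st))
        pts: list[tuple[float, float]] = []
        tries = 0
        while len(pts) < n_st:
            sx = cx + rng.uniform(-half, half)
            sy = cy + rng.uniform(-half, half)
            if all(np.hypot(sx - px, sy - py) >= min_spacing for px, py in pts):
                pts.append((sx, sy))
            else:
                tries += 1
                if tries > max_tries:
                    raise RuntimeError(
                        f"could not pack {n_st} stations {min_spacing / 1000:.1f} km "
                        f"apart in area {name}; enlarge the area extent")
        for k, (sx, sy) in enumerate(pts):
            placed.append((f"{name}-{k + 1:02d}", name, zone, sx, sy))
    trail_choices = np.array(["AT", "NT", "RD"])
    trail_p = np.array([0.7, 0.15, 0.15])
    stations = []
    for sid, area, zone, sx, sy in ((p[0], p[1], p[2], p[3], p[4]) for p in placed):
        stations.append(StationInfo(
            station_id=sid, x=sx, y=sy, area=area, zone=zone,
            trail_type=str(rng.choice(trail_choices, p=trail_p)),
            active_windows=[],
        ))
    return stations


def _blend(zone_val: float, pooled: float, s: float) -> float:
    # geometric interpolation between the pooled and the zone-specific level
    return float(np.exp(s * np.log(zone_val) + (1 - s) * np.log(pooled)))


def river_line() -> LineString:
    """Synthetic river polyline skirting the park's eastern boundary."""
    return LineString([(48_000.0, -5_000.0), (44_000.0, 20_000.0),
                       (47_000.0, 50_000.0)])


def simulate_covariates(stations, params: GradientParams | None = None,
                        seed=0) -> CovariateTable:
    """Draw unstandardized site covariates with zone gradients.

    Livestock counts are negative-binomial with a zone-dependent mean
    (near zero inside the park, heavy in village lands); CPUE is
    lognormal decreasing toward village lands; household locations
    cluster around village-land area centroids and the household distance
    is the Euclidean distance to the nearest one; river distance is the
    distance to a fixed synthetic river polyline near the park boundary.
    With ``strength = 0`` every covariate is drawn iid from its pooled
    marginal (no geography), making zones exchangeable.
    """
    params = params or GradientParams()
    rng = _rng(seed)
    s = float(params.strength)
    if not 0.0 <= s <= 1.0:
        raise ValueError("gradient strength must be in [0, 1]")
    zones = [st.zone for st in stations]
    n = len(stations)

    pooled_ls = float(np.exp(np.mean([np.log(max(v, 1e-3))
                                      for v in params.livestock_mean.values()])))
    pooled_cp = float(np.exp(np.mean([np.log(v) for v in params.cpue_median.values()])))

    k = params.livestock_dispersion
    means = np.array([_blend(max(params.livestock_mean[z], 1e-3), pooled_ls, s)
                      for z in zones])
    livestock = rng.negative_binomial(k, k / (k + means))

    medians = np.array([_blend(params.cpue_median[z], pooled_cp, s) for z in zones])
    cpue = np.exp(np.log(medians) + params.cpue_sigma * rng.standard_normal(n))

    if s == 0.0:
        dist_river = np.exp(rng.normal(np.log(15_000.0), 0.6, size=n))
        dist_household = np.exp(rng.normal(np.log(10_000.0), 0.8, size=n))
    else:
        river = river_line()
        import shapely

        pts = shapely.points([st.x for st in stations], [st.y for st in stations])
        dist_river = shapely.distance(pts, river)

        # household clusters around area centroids, density set by zone
        hh = []
        areas = {}
        for st in stations:
            areas.setdefault(st.area, []).append((st.x, st.y))
        for area, pts_a in areas.items():
            zone = next(st.zone for st in stations if st.area == area)
            n_hh = params.households_per_area[zone]
            if n_hh == 0:
                continue
            cx = float(np.mean([p[0] for p in pts_a]))
            cy = float(np.mean([p[1] for p in pts_a]))
            hh.append(np.column_stack([
                rng.normal(cx, params.household_spread, size=n_hh),
                rng.normal(cy, params.household_spread, size=n_hh),
            ]))
        if not hh:
            # no village/WMA areas in this layout: scatter a sparse
            # background of households over the station extent instead
            xs = np.array([st.x for st in stations])
            ys = np.array([st.y for st in stations])
            hh.append(np.column_stack([
                rng.uniform(xs.min() - 20_000, xs.max() + 20_000, size=10),
                rng.uniform(ys.min() - 20_000, ys.max() + 20_000, size=10),
            ]))
        hh = np.vstack(hh)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(hh).query(np.array([(st.x, st.y) for st in stations]))
        dist_household = d

    df = pd.DataFrame(
        {
            "livestock": livestock.astype(float),
            "dist_river": np.asarray(dist_river, dtype=float),
            "dist_household": np.asarray(dist_household, dtype=float),
            "cpue": cpue,
        },
        index=pd.Index([st.station_id for st in stations], name="station_id"),
    )[COVARIATE_COLUMNS]
    return CovariateTable(df)


DEFAULT_EFFORT_DAYS = {name: days for name, _, _, days in AREA_LAYOUT}
DEFAULT_SURVEY_START = date(2015, 6, 1)


def _assign_windows(stations, grid: OccasionGrid, effort_pattern, rng) -> None:
    total_days = grid.n_occasions * grid.occasion_days
    for st in stations:
        if effort_pattern == "full":
            days = total_days
        else:
            target = DEFAULT_EFFORT_DAYS.get(st.area, 60)
            days = int(np.clip(round(target * rng.uniform(0.8, 1.2)), 7, total_days))
        start_off = int(rng.integers(0, total_days - days + 1))
        start = grid.start + timedelta(days=start_off)
        st.active_windows = [(start, start + timedelta(days=days))]


def simulate_detection_data(stations, covariates: CovariateTable,
                            truth: SyntheticTruth | None = None,
                            grid: OccasionGrid | None = None,
                            effort_pattern: str = "ragged",
                            seed=0):
    """Simulate use, detection and record-level timestamps from the model.

    Covariates are standardized internally before the truth slopes are
    applied.  Area intercepts are drawn once from Normal(mu, tau^2) if the
    truth does not carry them already.  Every detected (site, occasion)
    cell emits one or more timestamps with gaps above the independence
    window, so the ingest path reproduces the history exactly.

    Returns ``(history, records, stations, truth)`` where ``truth`` holds
    the realized area effects.
    """
    truth = truth or SyntheticTruth()
    grid = grid or OccasionGrid(DEFAULT_SURVEY_START)
    rng = _rng(seed)
    if len(truth.alpha) != len(covariates.columns):
        raise ValueError(
            f"truth has {len(truth.alpha)} slopes for {len(covariates.columns)} covariates")

    if effort_pattern is not None:
        _assign_windows(stations, grid, effort_pattern, rng)
    effort = compute_effort(stations, grid, warn=False)

    z_table = covariates if covariates.standardized else zscore_standardize(covariates)
    X = z_table.data.reindex([s.station_id for s in stations]).to_numpy(dtype=float)

    areas = sorted({s.area for s in stations})
    if truth.area_effects is None:
        eff = {a: float(truth.mu + truth.tau * rng.standard_normal()) for a in areas}
        truth = SyntheticTruth(truth.mu, truth.tau, tuple(truth.alpha), truth.beta0,
                               tuple(truth.beta_k), eff, truth.seed)
    area_eff = np.array([truth.area_effects[s.area] for s in stations])

    eta = area_eff + X @ np.asarray(truth.alpha, dtype=float)
    psi = 1.0 / (1.0 + np.exp(-eta))
    trail_order = ["AT", "NT", "RD"]
    contrast = {"AT": 0.0, "NT": truth.beta_k[0], "RD": truth.beta_k[1]}
    p = np.array([1.0 / (1.0 + np.exp(-(truth.beta0 + contrast[s.trail_type])))
                  for s in stations])

    Z = (rng.random(len(stations)) < psi).astype(int)
    y = np.where(effort > 0, 0.0, np.nan)
    draws = rng.random(effort.shape)
    y[(effort > 0) & (draws < (Z * p)[:, None])] = 1.0

    records = _emit_records(stations, y, grid, rng)
    history = DetectionHistory([s.station_id for s in stations], y, effort, grid)
    return history, records, stations, truth


_GAP_MIN = 6  # minutes between synthetic timestamps, above the 5-min window


def _emit_records(stations, y, grid, rng, species="leopard"):
    records = []
    for i, st in enumerate(stations):
        for j in np.flatnonzero(y[i] == 1.0):
            os, oe = grid.occasion_bounds(int(j))
            active = [d for off in range((oe - os).days)
                      for d in [os + timedelta(days=off)]
                      if any(s <= d < e for s, e in st.active_windows)]
            n_rec = 1 + rng.poisson(0.5)
            slots = (len(active) * 24 * 60) // _GAP_MIN
            offs = rng.choice(slots, size=min(n_rec, slots), replace=False) * _GAP_MIN
            for off in sorted(int(o) for o in offs):
                day = active[off // (24 * 60)]
                minute = off % (24 * 60)
                ts = pd.Timestamp(day) + pd.Timedelta(minutes=minute)
                records.append(DetectionRecord(st.station_id, species, ts))
    return sorted(records)


def evaluate_recovery(fits, truths) -> pd.DataFrame:
    """Bias, RMSE, CI coverage and inclusion rates across replicates.

    ``fits`` are :class:`PosteriorDraws`, paired one-to-one with
    :class:`SyntheticTruth` entries.  Slopes and trail contrasts are
    judged on their model-averaged draws (``w * coef``); ``mu``, ``tau``
    and ``beta0`` on their plain draws.  ``mean_w`` is split-reported so
    true-zero and true-nonzero effects can be compared.
    """
    if len(fits) != len(truths):
        raise ValueError("fits and truths must pair one-to-one")
    if not fits:
        raise ValueError("no replicates supplied")
    per_param: dict[str, dict] = {}

    def add(name, true_val, est, lo, hi, w=None):
        rec = per_param.setdefault(name, {"true": [], "err": [], "cover": [], "w": []})
        rec["true"].append(true_val)
        rec["err"].append(est - true_val)
        rec["cover"].append(lo <= true_val <= hi)
        if w is not None:
            rec["w"].append(w)

    for draws, truth in zip(fits, truths):
        for name, val in (("mu", truth.mu), ("tau", truth.tau), ("beta0", truth.beta0)):
            flat = draws.get(name, pooled=True)
            add(name, val, flat.mean(), *np.percentile(flat, [2.5, 97.5]))
        ma = model_average_coefficients(draws)
        for c, nm in enumerate(draws.covariate_names):
            row = ma.loc[f"alpha[{nm}]"]
            add(f"alpha[{nm}]", truth.alpha[c], row["mean_model_avg"],
                row["ci_low_model_avg"], row["ci_high_model_avg"], row["w"])
        for t, nm in enumerate(draws.trail_labels):
            row = ma.loc[f"beta[{nm}]"]
            add(f"beta[{nm}]", truth.beta_k[t], row["mean_model_avg"],
                row["ci_low_model_avg"], row["ci_high_model_avg"], row["w"])

    rows = []
    for name, rec in per_param.items():
        err = np.asarray(rec["err"], dtype=float)
        rows.append({
            "parameter": name,
            "true_mean": float(np.mean(rec["true"])),
            "bias": float(err.mean()),
            "rmse": float(np.sqrt(np.mean(err**2))),
            "coverage": float(np.mean(rec["cover"])),
            "mean_w": float(np.mean(rec["w"])) if rec["w"] else np.nan,
            "n_replicates": len(err),
        })
    return pd.DataFrame(rows).set_index("parameter")
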