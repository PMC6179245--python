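"""Site-level covariate engineering for the site-use model.

Builds the per-station design matrix:

* **CPUE prey index** — a catch-per-unit-effort relative prey-availability
  index: independent prey events weighted by species body mass, divided by
  station trap-days and scaled to kg per 100 trap-days;
* **livestock presence** — pooled count of independent livestock events
  (each livestock species filtered for independence separately, then
  summed);
* **distance covariates** — distance to the river and to the nearest
  household, sampled from 500 m distance rasters;
* z-score standardization (sample SD, n-1 denominator) with stored
  means/SDs for back-transformation, and Pearson/VIF collinearity
  screening against the conventional <0.7 / <3 thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records_io import DetectionRecord, StationInfo, filter_independent

__all__ = [
    "DEFAULT_PREY_MASSES",
    "LIVESTOCK_SPECIES",
    "CovariateTable",
    "compute_cpue",
    "compute_livestock_presence",
    "zscore_standardize",
    "collinearity_screen",
]

# Editable default mean adult body masses (kg) for the five primary prey
# species, from standard East African mammal field-guide ranges.
DEFAULT_PREY_MASSES: dict[str, float] = {
    "bushbuck": 45.0,
    "common_duiker": 18.0,
    "greater_kudu": 200.0,
    "impala": 50.0,
    "warthog": 75.0,
}

LIVESTOCK_SPECIES: tuple[str, ...] = ("cattle", "goat", "donkey")

COVARIATE_COLUMNS = ["livestock", "dist_river", "dist_household", "cpue"]


@dataclass
class CovariateTable:
    """Per-station design matrix with standardization metadata.

    ``data`` is indexed by station_id.  When ``standardized`` is True every
    column has sample mean 0 and sample SD 1, and ``means``/``sds`` hold
    the constants needed to map back to natural units.
    """

    data: pd.DataFrame
    standardized: bool = False
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate station ids in covariate table")
        if self.standardized:
            mu = self.data.mean()
            sd = self.data.std(ddof=1)
            if (mu.abs() > 1e-8).any() or ((sd - 1).abs() > 1e-8).any():
                raise ValueError("standardized flag set but columns are not z-scored")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def station_ids(self) -> list[str]:
        return list(self.data.index.astype(str))

    def matrix(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def destandardize(self) -> "CovariateTable":
        """Invert z-scoring using the stored means/SDs."""
        if not self.standardized:
            return self
        raw = self.data.copy()
        for c in raw.columns:
            raw[c] = raw[c] * self.sds[c] + self.means[c]
        return CovariateTable(raw, standardized=False)


def compute_cpue(prey_records: Sequence[DetectionRecord],
                 effort_days: Mapping[str, float] | pd.Series,
                 mass_table: Mapping[str, float] | None = None,
                 *, prefiltered: bool = False,
                 window_minutes: float = 5.0) -> pd.Series:
    """Catch-per-unit-effort prey biomass index, kg per 100 trap-days.

    ``cpue_i = 100 * sum_s(N_is * mass_s) / effort_i`` where ``N_is`` is
    the number of independent events of prey species ``s`` at station
    ``i``.  Records of species absent from ``mass_table`` are ignored.
    Records at a station with zero recorded effort raise.
    """
    mass_table = dict(DEFAULT_PREY_MASSES if mass_table is None else mass_table)
    for sp, mass in mass_table.items():
        if mass <= 0:
            raise ValueError(f"non-positive mass for {sp}")
    effort = pd.Series(effort_days, dtype=float)
    recs = [r for r in prey_records if r.species in mass_table]
    if not prefiltered:
        recs = filter_independent(recs, window_minutes)
    biomass = pd.Series(0.0, index=effort.index)
    for r in recs:
        if r.station_id not in effort.index:
            raise ValueError(f"prey record at unknown station {r.station_id}")
        if effort[r.station_id] <= 0:
            raise ValueError(f"station {r.station_id} has prey records but zero effort")
        biomass[r.station_id] += mass_table[r.species]
    cpue = 100.0 * biomass / effort.where(effort > 0, np.nan)
    return cpue.fillna(0.0).rename("cpue")


def compute_livestock_presence(livestock_records: Sequence[DetectionRecord],
                               stations: Sequence[StationInfo],
                               species: Sequence[str] = LIVESTOCK_SPECIES,
                               *, prefiltered: bool = False,
                               window_minutes: float = 5.0) -> pd.Series:
    """Pooled count of independent livestock events per station.

    Each livestock species is independence-filtered separately (the 5-min
    chained gap rule), then counts are pooled across species.
    """
    recs = [r for r in livestock_records if r.species in set(species)]
    if not prefiltered:
        recs = filter_independent(recs, window_minutes)
    counts = pd.Series(0, index=pd.Index([s.station_id for s in stations], name="station_id"))
    for r in recs:
        if r.station_id in counts.index:
            counts[r.station_id] += 1
    return counts.rename("livestock")


def zscore_standardize(table: CovariateTable) -> CovariateTable:
    """Z-score every column (mean 0, sample SD 1, n-1 denominator).

    Idempotent; original means/SDs are stored so prediction curves can be
    drawn in natural units.  A constant column cannot be standardized and
    raises.
    """
    if table.standardized:
        return table
    data = table.data.astype(float)
    mu = data.mean()
    sd = data.std(ddof=1)
    bad = [c for c in data.columns if not np.isfinite(sd[c]) or sd[c] == 0]
    if bad:
        raise ValueError(f"cannot standardize constant column(s): {bad}")
    z = (data - mu) / sd
    return CovariateTable(z, standardized=True,
                          means=mu.to_dict(), sds=sd.to_dict())


def collinearity_screen(table: CovariateTable, r_max: float = 0.7,
                        vif_max: float = 3.0) -> dict:
    """Pairwise Pearson correlations and variance inflation factors.

    ``VIF_c = 1 / (1 - R^2_c)`` from regressing covariate ``c`` on all the
    others (with intercept).  A covariate passes if its largest absolute
    pairwise correlation is below ``r_max`` and its VIF below ``vif_max``.
    Perfect collinearity is reported as ``VIF = inf`` and fails.
    """
    X = table.matrix()
    n, k = X.shape
    if k < 2:
        raise ValueError("need at least two covariates to screen")
    if n <= k + 1:
        raise ValueError("need more observations than covariates + 1")
    cols = table.columns
    corr = pd.DataFrame(np.corrcoef(X, rowvar=False), index=cols, columns=cols)
    vifs = {}
    for j in range(k):
        yj = X[:, j]
        Xo = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Xo, yj, rcond=None)
        resid = yj - Xo @ beta
        sst = np.sum((yj - yj.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / sst if sst > 0 else 1.0
        vifs[cols[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    vif = pd.Series(vifs, name="vif")
    off = corr.where(~np.eye(k, dtype=bool)).abs().max()
    passed = (off < r_max) & (vif < vif_max)
    return {"pearson": corr, "vif": vif, "max_abs_r": off,
            "passed": passed, "r_max": r_max, "vif_max": vif_max}
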