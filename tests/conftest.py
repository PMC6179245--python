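from datetime import date

import numpy as np
import pandas as pd
import pytest

import siteuse
from siteuse import (CovariateTable, DetectionRecord, OccasionGrid, StationInfo)


def rec(station, species, ts):
    return DetectionRecord(station, species, pd.Timestamp(ts))


def make_station(sid="s1", x=0.0, y=0.0, area="A", zone="national_park",
                 trail="AT", windows=None):
    return StationInfo(sid, x, y, area, zone, trail, windows or [])


@pytest.fixture
def grid4():
    return OccasionGrid(date(2015, 6, 1), n_occasions=4)


@pytest.fixture(scope="session")
def survey():
    """One default synthetic survey with its fitted reduced-MCMC draws."""
    stations = siteuse.simulate_stations(seed=11)
    cov = siteuse.simulate_covariates(stations, seed=12)
    zcov = siteuse.zscore_standardize(cov)
    hist, records, stations, truth = siteuse.simulate_detection_data(
        stations, cov, seed=13)
    return {"stations": stations, "cov": cov, "zcov": zcov,
            "history": hist, "records": records, "truth": truth}


@pytest.fixture(scope="session")
def survey_fit(survey):
    settings = siteuse.McmcSettings.reduced(seed=21)
    return siteuse.run_mcmc(survey["history"], survey["zcov"],
                            survey["stations"], settings=settings)


def standardized_table(values: np.ndarray, ids=None, cols=None) -> CovariateTable:
    """Wrap an array as a z-scored covariate table."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ids = ids or [f"s{i+1}" for i in range(values.shape[0])]
    cols = cols or [f"x{j+1}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=pd.Index(ids, name="station_id"), columns=cols)
    return siteuse.zscore_standardize(CovariateTable(df))
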