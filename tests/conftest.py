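import numpy as np
import pytest

from aslt import (
    IndexMeasurementSeries,
    default_study_config,
    fit_arrhenius_twostep,
    generate_series,
    reference_rate_set,
)


@pytest.fixture(scope="session")
def k270_rates():
    """Published per-temperature K270 rate constants (absorbance/day)."""
    return reference_rate_set("K270")


@pytest.fixture(scope="session")
def k270_model(k270_rates):
    """Two-step log-linear Arrhenius model for K270."""
    return fit_arrhenius_twostep(k270_rates)


@pytest.fixture(scope="session")
def default_study():
    """One synthetic accelerated study at the default design, seed 0."""
    return generate_series(default_study_config(seed=0))


def make_series(times, values, index_id="K270", temperature=25.0, unit="AU",
                replicate=None):
    return IndexMeasurementSeries(
        index_id=index_id,
        temperature=temperature,
        times=np.asarray(times, float),
        values=np.asarray(values, float),
        unit=unit,
        replicate=replicate,
    )
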