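import numpy as np
import pytest

from calcmvpa.design import DesignSpec, build_conditions, build_predictor_rdms


@pytest.fixture(scope="session")
def spec():
    return DesignSpec()

@pytest.fixture(scope="session")
def conditions(spec):
    return build_conditions(spec)


@pytest.fixture(scope="session")
def predictors(conditions):
    return build_predictor_rdms(conditions)


@pytest.fixture(scope="session")
def noiseless():
    from calcmvpa.simulate import NoiseModel

    return NoiseModel(sigma=0.0, drift_order=0, drift_sigma=0.0)


def pearson_by_hand(x, y):
    """Textbook Pearson correlation, used as an independent oracle."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum()))
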