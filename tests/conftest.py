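import numpy as np
import pandas as pd
import pytest

import geograin as gg

TRUTH = gg.VariogramModel(nugget=0.2, partial_sill=0.8, range_a=30.0)


@pytest.fixture(scope="session")
def frame300():
    return gg.square_frame(side_km=300.0)


@pytest.fixture(scope="session")
def truth_model():
    return TRUTH


def random_field_survey(n, seed, model=TRUTH, mean=0.0, side_km=300.0,
                        n_close_pairs=0, log_scale=False):
    """Uniform locations in a square with one simulated field draw."""
    design = gg.SurveyDesign(gg.square_frame(side_km=side_km), n,
                             n_close_pairs, seed=seed)
    spec = gg.FieldSpec(mean, model, log_scale=log_scale, seed=seed)
    return gg.generate_grain_survey(design, spec, coverage=False)


@pytest.fixture(scope="session")
def field_survey_200():
    """200-point simulated field under the session truth model."""
    return random_field_survey(200, seed=11)


@pytest.fixture(scope="session")
def tiny_survey():
    """Small deterministic survey for interface-level tests."""
    rng = np.random.default_rng(5)
    n = 40
    return pd.DataFrame({
        "site_id": [f"S{i}" for i in range(n)],
        "lon": 36.0 + rng.uniform(0, 1.5, n),
        "lat": rng.uniform(0, 1.5, n),
        "value": rng.normal(10.0, 2.0, n),
    })
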