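import numpy as np
import pandas as pd
import pytest

from ecoconv import build_matrix, interpolate_surface, load_reference_knots


@pytest.fixture(scope="session")
def reference_knots():
    return load_reference_knots()


@pytest.fixture(scope="session")
def filled_reference_surface(reference_knots):
    surf = build_matrix(list(reference_knots.itertuples(index=False, name=None)))
    return interpolate_surface(surf)


@pytest.fixture
def noiseless_decay_table():
    """Observation table sampled exactly from S(t) = 9.09 exp(-0.19 t), %BW."""
    t = np.repeat(np.arange(11.0), 3)
    weight = 40.0
    pct = 9.09 * np.exp(-0.19 * t)
    return pd.DataFrame(
        {
            "fish_id": np.arange(t.size),
            "condition": "in situ",
            "day": 0,
            "time_h": t,
            "body_weight_g": weight,
            "stomach_content_g": pct / 100.0 * weight,
            "temperature_C": 25.1,
        }
    )
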