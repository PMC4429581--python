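import numpy as np
import pandas as pd
import pytest

import budsizer as bz


@pytest.fixture(scope="session")
def glucose_model2():
    """Small glucose culture, bud-localised variant."""
    return bz.make_fixture("model2-glucose", seed=3)


@pytest.fixture(scope="session")
def glucose_model2_records(glucose_model2):
    return glucose_model2.records_frame()


@pytest.fixture()
def toy_records():
    """Hand-built cycle table with known durations and volumes."""
    rows = [
        # cell, age, role, t_birth, t_start, t_div, v_birth, v_start, v_div, v_bud
        (0, 0, "daughter", 0.0, 50.0, 118.0, 30.0, 45.0, 70.0, 25.0),
        (1, 1, "mother", 118.0, 148.0, 216.0, 45.0, 60.0, 90.0, 36.0),
        (2, 2, "mother", 216.0, 242.0, 310.0, 54.0, 66.0, 99.0, 38.0),
        (3, 0, "daughter", 118.0, 188.0, 260.0, 25.0, 40.0, 64.0, 24.0),
    ]
    df = pd.DataFrame(rows, columns=[
        "cell_id", "replicative_age", "role", "t_birth", "t_start",
        "t_division", "v_birth", "v_start", "v_division", "v_bud"])
    df["t_g1"] = df.t_start - df.t_birth
    df["t_sg2m"] = df.t_division - df.t_start
    df["generation_time"] = df.t_division - df.t_birth
    df["condition"] = "glucose"
    df["variant"] = "model2"
    return df


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
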