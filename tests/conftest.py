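import logging

import numpy as np
import pandas as pd
import pytest

import pegf

logging.getLogger("pegf").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def school_specs():
    return pegf.school_specs()


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced cohort for fast unit tests; study-scale runs live in
    the acceptance suite."""
    return pegf.SyntheticConfig(n_units=120, n_pilot=12)


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return pegf.generate_panel(small_cfg, seed=11)


@pytest.fixture(scope="session")
def toy_system():
    return pegf.feedback_toy()


def tiny_two_var_panel(n=40, p_x=0.75, y_values=None, T=2, seed=0):
    """Minimal hand-built panel: one binary covariate x, one outcome y."""
    rng = np.random.default_rng(seed)
    specs = [
        pegf.CovariateSpec("x", "confounder", "binary", sim_order=0),
        pegf.CovariateSpec("y", "outcome", "bounded_continuous",
                           sim_order=1, bounds=(0, 1)),
    ]
    rows = {"unit_id": np.repeat(np.arange(n), T + 1),
            "time": np.tile(np.arange(T + 1), n)}
    k = int(round(p_x * n))
    x = np.zeros((n, T + 1))
    x[:k, 1:] = 1.0
    rows["x"] = x.ravel()
    if y_values is None:
        y = rng.uniform(0.2, 0.8, size=(n, T + 1))
    else:
        y = np.broadcast_to(np.asarray(y_values, dtype=float), (n, T + 1)).copy()
    rows["y"] = y.ravel()
    return pegf.SchoolPanel(pd.DataFrame(rows), specs)
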