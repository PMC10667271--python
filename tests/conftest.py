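import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import desiccnet as d

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_config():
    return d.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def expression_data(default_config):
    """Expression matrix + sample sheet + truth under default conditions."""
    return d.generate_expression(default_config)


@pytest.fixture(scope="session")
def deg_tables(expression_data):
    expr, samples, _ = expression_data
    return {
        tissue: d.deg_tables_for_tissue(expr, samples, tissue)
        for tissue in ("shoot", "root")
    }


def bh_step_up(p):
    """Brute-force Benjamini-Hochberg step-up adjustment (oracle)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


def pearson_brute_force(x):
    """All-pairs Pearson r by the covariance/SD definition (oracle)."""
    n_genes = x.shape[0]
    out = np.eye(n_genes)
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            a, b = x[i] - x[i].mean(), x[j] - x[j].mean()
            r = (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum())
            out[i, j] = out[j, i] = r
    return out
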