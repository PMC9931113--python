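import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20230215)


@pytest.fixture
def small_design(rng):
    """9 observations in 3 groups, d=2, m=2."""
    from oracles import random_grouped_design

    return random_grouped_design(rng, n=9, d=2, J=3, m=2)


@pytest.fixture(scope="session")
def radon_like_csv(tmp_path_factory):
    """A synthetic radon-style CSV (county, floor, activity, Uppm).

    A stand-in with the same column dialect and value ranges as the
    Minnesota radon survey data, generated from a known intercept-deviation
    model; it is NOT the real dataset.
    """
    rng = np.random.default_rng(404)
    J = 12
    counties = [f"C{j:02d}" for j in range(J)]
    u = np.exp(rng.normal(0.0, 0.4, size=J))
    eta = rng.normal(0.0, 0.3, size=J)
    rows = []
    sizes = np.maximum(rng.poisson(15, size=J), 2)
    for j in range(J):
        for _ in range(sizes[j]):
            t = int(rng.random() < 0.2)
            lr = 1.3 - 0.6 * t + 0.4 * np.log(u[j]) + eta[j] + rng.normal(0, 0.7)
            rows.append((counties[j], t, float(np.exp(lr)), float(u[j])))
    df = pd.DataFrame(rows, columns=["county", "floor", "activity", "Uppm"])
    path = tmp_path_factory.mktemp("radon") / "synthetic_radon.csv"
    df.to_csv(path, index=False)
    return path
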