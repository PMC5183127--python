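import numpy as np
import pandas as pd
import pytest

from sadcompare.distributions import make_distribution
from sadcompare.fitting import Community


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_small_communities(n=20, max_s=30, seed=99):
    """Small communities drawn from all four families, for oracle checks."""
    out = []
    master = np.random.default_rng(seed)
    settings = [
        ("logseries", {"p": 0.9}),
        ("poisson_lognormal", {"mu": 1.0, "sigma": 1.0}),
        ("neg_binom", {"k": 1.5, "q": 0.3}),
        ("zipf", {"s": 1.8}),
    ]
    for i in range(n):
        fam, params = settings[i % len(settings)]
        S = int(master.integers(8, max_s + 1))
        x = make_distribution(fam, **params).sample(S, master)
        out.append(Community(f"oracle_{i}", x, dataset_id=fam))
    return out


@pytest.fixture(scope="session")
def small_communities():
    return random_small_communities()


@pytest.fixture
def fixture_csv(tmp_path):
    """Three-site long-format community CSV."""
    rows = []
    gen = np.random.default_rng(3)
    for s in range(3):
        x = make_distribution("logseries", p=0.95).sample(30, gen)
        for j, n in enumerate(x):
            rows.append({"site_id": f"s{s}", "species_id": f"sp{j}",
                         "abundance": int(n)})
    path = tmp_path / "threesites.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
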