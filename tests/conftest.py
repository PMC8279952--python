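import numpy as np
import pandas as pd
import pytest

from dyadkin.core import MethylomeTable, RegionSet
from dyadkin.simulate import SimulationConfig, build_toy_genome


def quick_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A scaled-down study layout for fast tests."""
    defaults = dict(
        seed=seed,
        contig_length=800_000,
        coverage_mean=20.0,
        n_reads=400,
        n_features={
            "IAPEz_int": 20, "IAP_LTR": 10, "ERV1": 5, "LINE": 10,
            "SINE": 15, "CGI": 10, "gene": 5,
        },
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def small_genome():
    return build_toy_genome(quick_config(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_methylome(rng, n=500, contig="chr1", max_pos=100_000) -> MethylomeTable:
    pos = np.sort(rng.choice(max_pos // 2, size=n, replace=False)) * 2
    cov = rng.poisson(20, size=n) + 1
    m = rng.binomial(cov, rng.uniform(0, 1, size=n))
    return MethylomeTable(
        pd.DataFrame({"contig": contig, "pos": pos, "count_M": m, "count_U": cov - m})
    )


def regions(rows) -> RegionSet:
    return RegionSet(
        pd.DataFrame(rows, columns=["contig", "start", "end", "label"][: len(rows[0])])
    )
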