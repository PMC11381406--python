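import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from droughtadapt import PopulationMeans, make_worked_fixture, summarize_means

DATA = Path(__file__).parent / "data"

# population means printed for the 206-genotype barley screen (mg)
PRINTED_PM = PopulationMeans(c_bar=746.90, t_bar=285.40, n_genotypes=206)


@pytest.fixture(scope="session")
def worked_tm() -> pd.DataFrame:
    return make_worked_fixture()


@pytest.fixture(scope="session")
def worked_means(worked_tm):
    return summarize_means(worked_tm)


@pytest.fixture(scope="session")
def worked_expected() -> pd.DataFrame:
    """Frozen index table for the worked fixture, from an exact-arithmetic oracle."""
    return pd.read_csv(DATA / "worked_fixture_expected.csv")


def random_genotype_means(rng: np.random.Generator, n: int | None = None) -> pd.DataFrame:
    """A random valid GenotypeMeans frame in the drought regime (T < C on average)."""
    n = n or int(rng.integers(4, 40))
    c = rng.lognormal(mean=6.5, sigma=0.3, size=n)
    dc = rng.beta(1.6, 2.4, size=n)
    return pd.DataFrame({"genotype": [f"g{i}" for i in range(n)], "C": c, "T": c * dc})


def population_means_of(gm: pd.DataFrame) -> PopulationMeans:
    return PopulationMeans(
        c_bar=float(gm["C"].mean()), t_bar=float(gm["T"].mean()), n_genotypes=len(gm)
    )
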