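import numpy as np
import pytest

from mirhub.de import CountMatrix
from mirhub.simulate import default_study_config, simulate_counts


@pytest.fixture(scope="session")
def study_config():
    return default_study_config(seed=11)


@pytest.fixture(scope="session")
def study_counts(study_config):
    return simulate_counts(study_config)


@pytest.fixture()
def random_count_matrix():
    """Small dense random matrix with both groups labelled."""

    def make(seed=0, n_mirnas=20, n_per_group=4):
        rng = np.random.default_rng(seed)
        import pandas as pd

        samples = [f"c{i}" for i in range(n_per_group)] + [f"t{i}" for i in range(n_per_group)]
        groups = {s: ("control" if s.startswith("c") else "treated") for s in samples}
        df = pd.DataFrame(
            rng.integers(0, 500, size=(n_mirnas, 2 * n_per_group)),
            index=[f"rno-miR-{i}-3p" for i in range(n_mirnas)],
            columns=samples,
        )
        return CountMatrix(df, groups)

    return make
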