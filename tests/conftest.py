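import warnings

import numpy as np
import pandas as pd
import pytest

from symptomnet import (
    GeneratorConfig,
    build_precision,
    sample_responses,
    study_config,
)

# sklearn's glasso emits convergence warnings at the smallest penalties of a
# long path; they are harmless for EBIC selection and would drown test output.
warnings.filterwarnings("ignore", message=".*graphical_lasso.*")


@pytest.fixture(scope="session")
def study_cfg():
    return study_config(seed=11)


@pytest.fixture(scope="session")
def study_spec(study_cfg):
    return build_precision(study_cfg)


@pytest.fixture(scope="session")
def study_table(study_cfg, study_spec):
    return sample_responses(study_spec, study_cfg)


def small_config(seed=0, n=500, within=0.25, bridge=0.3, levels=4):
    """Two 4-node blocks joined by one bridge edge: a fast, well-separated net."""
    return GeneratorConfig(
        n_respondents=n,
        blocks=[("A", 4, within), ("B", 4, within)],
        bridge_edges=[(0, 4, bridge)],
        item_levels=[levels] * 8,
        min_codes=[1] * 8,
        seed=seed,
    )


@pytest.fixture
def small_cfg():
    return small_config()


@pytest.fixture
def small_table(small_cfg):
    return sample_responses(build_precision(small_cfg), small_cfg)
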