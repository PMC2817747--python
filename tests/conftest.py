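import numpy as np
import pandas as pd
import pytest

from breastmarker import synthetic as syn


@pytest.fixture(scope="session")
def study_cohort():
    """Synthetic validation cohort at the study conditions (fixed seed)."""
    cfg = syn.study_cohort_config(seed=3)
    matrix, ann = syn.gen_cohort(cfg)
    return cfg, matrix, ann


@pytest.fixture()
def balanced_nested():
    """Tiny balanced 2-woman x 2-breast x 2-slice dataset with known values."""
    vals = iter([1.0, 1.2, 2.0, 2.1, 5.0, 5.3, 6.0, 6.4])
    rows = [
        ("G", w, b, s, next(vals))
        for w in ("W1", "W2")
        for b in ("L", "R")
        for s in ("S1", "S2")
    ]
    return pd.DataFrame(rows, columns=["gene", "woman", "breast", "slice", "value"])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
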