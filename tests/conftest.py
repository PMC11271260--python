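import numpy as np
import pandas as pd
import pytest

import fusebench as fb


@pytest.fixture(scope="session")
def small_synth():
    """Small complementary-signal cohort shared across pipeline tests."""
    cfg = fb.complementary_config(seed=42, n_subjects=240, block_dims=(10, 12),
                                  n_informative=(4, 5), nuisance_factors=(2, 2))
    return fb.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_synth):
    return small_synth.cohort


def make_table(name, n, p, rng, missing_rate=0.0, dates=None, prefix="f"):
    """Random modality table helper for preprocessing tests."""
    X = rng.normal(size=(n, p))
    if missing_rate > 0:
        X = np.where(rng.random((n, p)) < missing_rate, np.nan, X)
    idx = pd.Index([f"S{i:03d}" for i in range(n)], name="subject_id")
    df = pd.DataFrame(X, index=idx, columns=[f"{prefix}{j}" for j in range(p)])
    return fb.ModalityTable(name, df, dates)
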