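import numpy as np
import pandas as pd
import pytest

from metaboqc import (FeatureRecord, MSDataset, SampleRecord, SyntheticConfig,
                      generate_ms_dataset)


def make_dataset(values, sample_records, mz=None, rt=None, feature_ids=None,
                 log_transformed=False):
    """Small helper to hand-build an MSDataset from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    assert n_samp == len(sample_records)
    fids = feature_ids or [f"F{i + 1}" for i in range(n_feat)]
    feats = [FeatureRecord(fids[i],
                           mz=100.0 + 10 * i if mz is None else mz[i],
                           rt=60.0 + 30 * i if rt is None else rt[i])
             for i in range(n_feat)]
    df = pd.DataFrame(values, index=fids, columns=[s.id for s in sample_records])
    return MSDataset(df, sample_records, feats, log_transformed=log_transformed)


def bio(n, start_order=1):
    return [SampleRecord(f"s{i + 1}", "sample", start_order + i) for i in range(n)]


@pytest.fixture(scope="session")
def default_synth():
    """The default synthetic study (42 bio samples, QC every 5, 5% noise)."""
    return generate_ms_dataset(SyntheticConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
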