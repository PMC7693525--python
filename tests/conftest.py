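import logging

import numpy as np
import pytest
from hypothesis import settings

import qpcrmiss as q

logging.getLogger("qpcrmiss").setLevel(logging.ERROR)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_dataset(cq, sample_type, detection_limit=40.0, batch=None, is_control=None):
    """Build a QpcrDataset from a raw matrix; NaN entries are non-detects."""
    cq = np.asarray(cq, dtype=float)
    detected = np.isfinite(cq) & (cq < detection_limit)
    G, N = cq.shape
    return q.QpcrDataset(
        cq=cq,
        detected=detected,
        genes=np.array([f"g{i + 1}" for i in range(G)], dtype=object),
        samples=np.array([f"s{j + 1}" for j in range(N)], dtype=object),
        sample_type=np.asarray(sample_type, dtype=object),
        detection_limit=detection_limit,
        batch=None if batch is None else np.asarray(batch, dtype=object),
        is_control=None if is_control is None else np.asarray(is_control, dtype=bool),
    )


@pytest.fixture
def two_group_ds():
    """2 genes x (2 groups of 3 replicates), one non-detect in gene 2."""
    cq = np.array(
        [
            [28.1, 27.6, 28.4, 30.2, 29.8, 30.5],
            [34.0, 33.5, 34.8, 36.1, np.nan, 35.6],
        ]
    )
    return make_dataset(cq, ["A", "A", "A", "B", "B", "B"])


@pytest.fixture(scope="session")
def sim_fit():
    """A simulated 16-gene dataset (estimable genes only) with its DirEst fit."""
    ds, truth = q.simulate_dataset(16, 6, 6, seed=5)
    codes, _ = ds.group_codes()
    keep = np.ones(ds.n_genes, bool)
    for k in range(len(ds.groups)):
        keep &= ds.detected[:, codes == k].any(axis=1)
    ds = ds.subset(gene_mask=keep)
    fit, mech = q.direst(ds)
    return ds, fit, mech, truth
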