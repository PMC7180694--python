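import numpy as np
import pytest

from enosedrift import SampleSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sampleset(
    n_per_batch=(4, 4),
    n_features=3,
    seed=0,
    with_eval=True,
):
    """Small labeled-source / unlabeled-target SampleSet for unit tests."""
    rng = np.random.default_rng(seed)
    feats, batches, labels, concs, src = [], [], [], [], []
    for b, n in enumerate(n_per_batch, start=1):
        feats.append(rng.normal(0, 1, (n, n_features)))
        batches.extend([b] * n)
        labels.extend((np.arange(n) % 2 + 1).tolist())
        concs.extend(rng.uniform(10, 1000, n).tolist())
        src.extend([b == 1] * n)
    y = np.array(labels)
    is_source = np.array(src)
    return SampleSet(
        features=np.vstack(feats),
        batch_ids=np.array(batches),
        labels=np.where(is_source, y, -1),
        concentrations=np.where(is_source, np.array(concs), np.nan),
        is_source=is_source,
        eval_labels=y if with_eval else None,
        eval_concentrations=np.array(concs) if with_eval else None,
    )


@pytest.fixture
def small_sampleset():
    return make_sampleset()
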