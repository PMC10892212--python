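import numpy as np
import pytest

from qsarmlr import DescriptorDataset, load_reference_data


@pytest.fixture(scope="session")
def reference():
    """The packaged triazole study data (33 synthesized + 7 designed)."""
    return load_reference_data()


@pytest.fixture(scope="session")
def reference_train(reference):
    return reference.synthesized.training_set()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240219)


def make_dataset(X, y=None, split=None, prefix="d"):
    """Small helper: wrap a raw matrix in a DescriptorDataset."""
    X = np.asarray(X, dtype=float)
    return DescriptorDataset(
        compound_ids=[f"C{i}" for i in range(X.shape[0])],
        descriptor_names=[f"{prefix}{j}" for j in range(X.shape[1])],
        X=X,
        y=y,
        split=split,
    )
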