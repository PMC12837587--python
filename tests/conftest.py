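import numpy as np
import pytest

from infofolds import FrequencyDistribution, JointTable, holobiont_select, toy_model


@pytest.fixture(scope="session")
def toy():
    """The packaged 2x2 holobiont example: (q, W, q_post, partition)."""
    return toy_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


def random_simplex(rng, n, floor=1e-6):
    """Strictly interior random simplex point (avoids zero-support errors)."""
    v = rng.dirichlet(np.ones(n)) + floor
    return v / v.sum()


def random_pair(rng, n=4):
    labels = tuple(f"s{i}" for i in range(n))
    return (
        FrequencyDistribution(labels, random_simplex(rng, n)),
        FrequencyDistribution(labels, random_simplex(rng, n)),
    )


def random_table_pair(rng, shape=(2, 3)):
    names = ("host", "M1")
    labels = (tuple(f"H{i}" for i in range(shape[0])),
              tuple(f"m{j}" for j in range(shape[1])))
    n = int(np.prod(shape))
    q = JointTable(names, labels, random_simplex(rng, n).reshape(shape))
    qp = JointTable(names, labels, random_simplex(rng, n).reshape(shape))
    return q, qp


def product_table_step(rng, shape=(2, 3)):
    """Product-form initial table plus a positive-fitness selection step."""
    names = ("host", "M1")
    labels = (tuple(f"H{i}" for i in range(shape[0])),
              tuple(f"m{j}" for j in range(shape[1])))
    margs = [FrequencyDistribution(lab, random_simplex(rng, len(lab))) for lab in labels]
    q = JointTable.product(margs, axis_names=names)
    W = np.exp(rng.normal(0, 0.5, size=shape))
    q_post, _ = holobiont_select(q, W)
    return q, q_post, W
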