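import numpy as np
import pytest

from fedmtl import Case1Spec, TaskDataset, create_session, gen_case1


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_datasets(T=3, p=8, n=30, seed=0, loss="ls"):
    """Small well-conditioned cohorts (n > p) for oracle comparisons."""
    rng = np.random.default_rng(seed)
    names = [f"g{i}" for i in range(p)]
    datasets = []
    for t in range(T):
        X = rng.standard_normal((n, p))
        w = rng.standard_normal(p) * (rng.uniform(size=p) < 0.5)
        if loss == "ls":
            y = X @ w + 0.5 * rng.standard_normal(n)
        else:
            prob = 1.0 / (1.0 + np.exp(-(X @ w)))
            y = np.where(rng.uniform(size=n) < prob, 1.0, -1.0)
            if np.all(y == y[0]):  # ensure both classes
                y[0] = -y[0]
        datasets.append(TaskDataset(X=X, y=y, feature_names=names, task_id=f"task{t}"))
    return datasets


@pytest.fixture
def small_session():
    return create_session(make_datasets())


@pytest.fixture
def case1_small():
    spec = Case1Spec(T=3, p=40, n_per_task=25, seed=7)
    return gen_case1(spec)
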