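import numpy as np
import pandas as pd
import pytest

from wlgs.contacts import ContactTensor, DailyContactMatrix


def make_tensor(directed: np.ndarray, sensors=None, rule="union", day=1,
                epoch_start=0) -> ContactTensor:
    """Build a ContactTensor from a (n_epochs, n, n) directed array."""
    directed = np.asarray(directed, dtype=bool)
    n = directed.shape[1]
    if sensors is None:
        sensors = [chr(ord("A") + i) for i in range(n)]
    epochs = np.arange(epoch_start, epoch_start + 5 * directed.shape[0], 5)
    return ContactTensor(day=day, sensors=list(sensors), epochs=epochs,
                         directed=directed, rule=rule)


def random_tensor(rng: np.random.Generator, n_epochs=200, n=6, density=0.25,
                  rule="union") -> ContactTensor:
    d = rng.random((n_epochs, n, n)) < density
    return make_tensor(d, rule=rule)


def daily_matrix(t_ab: dict, T: float, day=1) -> DailyContactMatrix:
    pairs = [tuple(sorted(p)) for p in t_ab]
    vals = list(t_ab.values())
    members = {m for p in pairs for m in p}
    s = pd.Series(vals, index=pd.Index(pairs, tupleize_cols=False), dtype=float)
    return DailyContactMatrix(day=day, t_ab=s, T=T, n_crew=len(members))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
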