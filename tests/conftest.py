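import numpy as np
import pandas as pd
import pytest

from tegrn.synthetic import PlantedNetwork, SamplingDesign, simulate


def brute_force_te(x, y, n_bins, log_base=2.0):
    """Independent oracle: enumerate every (x_{n+1}, x_n, y_n) triple and
    evaluate the first-order transfer-entropy sum term by term."""
    from collections import Counter

    from tegrn.te_core import discretize

    xs, ys = discretize(np.asarray(x, float), n_bins), discretize(np.asarray(y, float), n_bins)
    n = len(xs)
    joint = Counter(zip(xs[1:], xs[:-1], ys[:-1]))
    fut_past = Counter(zip(xs[1:], xs[:-1]))
    past_pair = Counter(zip(xs[:-1], ys[:-1]))
    past = Counter(xs[:-1])
    total = n - 1
    s = 0.0
    for (f, a, b), c in joint.items():
        s += (c / total) * np.log(c * past[a] / (fut_past[(f, a)] * past_pair[(a, b)]))
    return s / np.log(log_base)


def pairwise_auroc(scores, labels):
    """Independent AUROC oracle: rank statistic over every positive-negative
    score pair, ties at half credit."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


@pytest.fixture
def toy_matrix():
    """5-gene toy with two constant rows."""
    rng = np.random.default_rng(11)
    data = {
        "gA": rng.normal(5, 1, 20),
        "gB": np.full(20, 3.0),
        "gC": np.arange(20, dtype=float),
        "gD": np.full(20, 0.0),
        "gE": rng.normal(2, 0.5, 20),
    }
    return pd.DataFrame(data).T.rename(columns=lambda c: f"t{c}")


def planted_simulation(seed, n_genes=10, n_edges=10, coupling=0.8, mode="nonlinear-lag"):
    """A random planted network and its simulated 480-point expression matrix."""
    names = tuple(f"G{i}" for i in range(n_genes))
    pairs = [(a, b) for a in names for b in names if a != b]
    rng = np.random.default_rng(seed + 7919)
    chosen = [pairs[i] for i in rng.choice(len(pairs), size=n_edges, replace=False)]
    net = PlantedNetwork(genes=names, edges={p: coupling for p in chosen}, mode=mode)
    matrix, gold = simulate(net, SamplingDesign(), seed=seed)
    return net, matrix, gold


@pytest.fixture
def planted():
    return planted_simulation(seed=1)
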