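"""Shannon entropy and plug-in transfer entropy for discretized time series.

Transfer entropy T(y→x) measures how much the past of a source series ``y``
reduces uncertainty about the next value of a target series ``x`` beyond what
the target's own past already explains:

    T(y→x) = Σ p(x_{n+1}, x_n^{(k)}, y_n^{(l)})
               · log2 [ p(x_{n+1} | x_n^{(k)}, y_n^{(l)}) / p(x_{n+1} | x_n^{(k)}) ]

with k and l the history (lag) orders of the target and source. With
k = l = 1 both series are treated as first-order Markov processes, which is
the default regime here. All probabilities are plug-in estimates from a
single joint count table over equal-width histogram symbols, so the estimate
is guaranteed non-negative and zero-probability cells contribute nothing.

Entropies and transfer entropies are reported in bits (log base 2) by
default; natural log is available via ``log_base``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TEPair",
    "shannon_entropy",
    "discretize",
    "transfer_entropy",
    "te_pair",
    "net_information_flow",
]

DEFAULT_N_BINS = 4


@dataclass(frozen=True)
class TEPair:
    """Bidirectional transfer entropy between two series.

    ``net_flow = te_y_to_x - te_x_to_y``; a positive value means the net
    information flow runs from y to x (y drives x).
    """

    te_y_to_x: float
    te_x_to_y: float
    k: int = 1
    l: int = 1

    @property
    def net_flow(self) -> float:
        return self.te_y_to_x - self.te_x_to_y


def shannon_entropy(distribution, log_base: float = 2.0) -> float:
    """Shannon entropy H = −Σ p·log p of a probability vector, in bits.

    Zero probabilities contribute 0 (the p·log p → 0 limit). Raises
    ``ValueError`` for negative entries or a vector not summing to 1.
    """
    p = np.asarray(distribution, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("distribution must be a non-empty 1-D probability vector")
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError(f"probabilities must sum to 1, got {total!r}")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)) / np.log(log_base))


def discretize(series, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Map a numeric series to integer symbols via equal-width binning.

    Bins span [min, max]; the top bin edge is closed so the maximum value is
    always assigned to bin ``n_bins - 1``. A constant series maps to a single
    symbol (bin 0).
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot discretize an empty series")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(x.size, dtype=np.int64)
    sym = np.floor((x - lo) / (hi - lo) * n_bins).astype(np.int64)
    np.clip(sym, 0, n_bins - 1, out=sym)
    return sym


def _encode_history(symbols: np.ndarray, order: int, n_bins: int, m: int) -> np.ndarray:
    """Integer-encode sliding histories of length ``order`` ending at t-1.

    Returns one code per prediction time t = m .. n-1, where m = max lag.
    """
    n = symbols.size
    codes = np.zeros(n - m, dtype=np.int64)
    for j in range(order):
        # value at t-1-j for t in [m, n)
        codes = codes * n_bins + symbols[m - 1 - j : n - 1 - j]
    return codes


def _te_from_symbols(
    target: np.ndarray,
    source: np.ndarray,
    k: int,
    l: int,
    n_bins: int,
    log_base: float = 2.0,
) -> float:
    """Plug-in transfer entropy T(source→target) from symbol series.

    Builds one joint count table over (target_{t}, target-history, source-
    history) tuples; every marginal is summed out of that same table.
    """
    m = max(k, l)
    n = target.size
    fut = target[m:]
    th = _encode_history(target, k, n_bins, m)
    sh = _encode_history(source, l, n_bins, m)
    bk = n_bins**k
    bl = n_bins**l
    joint = np.bincount(
        (fut * bk + th) * bl + sh, minlength=n_bins * bk * bl
    ).reshape(n_bins, bk, bl)
    total = n - m
    c_fth = joint  # (future, target-hist, source-hist)
    c_th_sh = joint.sum(axis=0)  # (target-hist, source-hist)
    c_fth_th = joint.sum(axis=2)  # (future, target-hist)
    c_th = joint.sum(axis=(0, 2))  # (target-hist,)

    nz = c_fth > 0
    f_idx, t_idx, s_idx = np.nonzero(nz)
    c = c_fth[nz].astype(float)
    # T = Σ p(f,th,sh) log [ c(f,th,sh)·c(th) / (c(f,th)·c(th,sh)) ]
    ratio = (c * c_th[t_idx]) / (c_fth_th[f_idx, t_idx] * c_th_sh[t_idx, s_idx])
    te = float(np.sum(c * np.log(ratio)) / (total * np.log(log_base)))
    # clamp tiny negative rounding noise; the plug-in estimate is >= 0
    return max(te, 0.0)


def _validate_pair(x: np.ndarray, y: np.ndarray, k: int, l: int) -> None:
    if x.size != y.size:
        raise ValueError(f"series lengths differ: {x.size} vs {y.size}")
    if k < 1 or l < 1:
        raise ValueError("lag orders k and l must be >= 1")
    if x.size - max(k, l) < 1:
        raise ValueError("series too short for the requested lag orders")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("series contain non-finite values")


def transfer_entropy(
    source,
    target,
    k: int = 1,
    l: int = 1,
    n_bins: int = DEFAULT_N_BINS,
    log_base: float = 2.0,
) -> float:
    """Transfer entropy T(source→target) in bits.

    ``k`` is the target-history order and ``l`` the source-history order;
    the default k = l = 1 treats both series as first-order Markov.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    _validate_pair(src, tgt, k, l)
    return _te_from_symbols(
        discretize(tgt, n_bins), discretize(src, n_bins), k, l, n_bins, log_base
    )


def te_pair(
    x,
    y,
    k: int = 1,
    l: int = 1,
    n_bins: int = DEFAULT_N_BINS,
    log_base: float = 2.0,
) -> TEPair:
    """Both directed transfer entropies between series x and y."""
    return TEPair(
        te_y_to_x=transfer_entropy(y, x, k, l, n_bins, log_base),
        te_x_to_y=transfer_entropy(x, y, k, l, n_bins, log_base),
        k=k,
        l=l,
    )


def net_information_flow(pair: TEPair) -> tuple[float, str]:
    """Signed net flow and direction label for a TEPair.

    Positive net flow means information runs y→x (y is the driver); negative
    means x→y; exactly zero assigns no direction.
    """
    flow = pair.net_flow
    if flow > 0:
        label = "y->x"
    elif flow < 0:
        label = "x->y"
    else:
        label = "undirected"
    return flow, label
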