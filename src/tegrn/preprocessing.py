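"""Centered moving-average smoothing and uninformative-gene filtering.

Raw expression time courses carry sporadic outliers from sampling and
measurement; a centered moving average F_t = mean(A_{t-n} .. A_{t+n}) over a
window of 2n+1 points suppresses them while preserving the slow rhythmic
trend. Genes whose expression never changes (standard deviation at or below
a floor, default exactly zero) carry no temporal information and are dropped
before any entropy estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SmoothingConfig", "moving_average", "smooth_matrix", "filter_uninformative_genes"]

DEFAULT_WINDOW = 5


@dataclass(frozen=True)
class SmoothingConfig:
    """Window must be odd (2n+1). boundary_policy: "shrink" averages only the
    in-range part of the window near the edges; "reflect" mirrors the series."""

    window: int = DEFAULT_WINDOW
    boundary_policy: str = "shrink"

    def __post_init__(self):
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be a positive odd integer, got {self.window}")
        if self.boundary_policy not in ("shrink", "reflect"):
            raise ValueError(f"unknown boundary policy {self.boundary_policy!r}")


def moving_average(series, config: SmoothingConfig | None = None) -> np.ndarray:
    """Centered moving average; output has the same length as the input."""
    cfg = config or SmoothingConfig()
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("series must be a non-empty 1-D array")
    if cfg.window > x.size:
        raise ValueError(f"window {cfg.window} exceeds series length {x.size}")
    half = cfg.window // 2
    if cfg.boundary_policy == "reflect":
        padded = np.pad(x, half, mode="reflect")
        kernel = np.full(cfg.window, 1.0 / cfg.window)
        return np.convolve(padded, kernel, mode="valid")
    # shrink: divide the windowed sum by the number of in-range points
    padded = np.pad(x, half, mode="constant")
    sums = np.convolve(padded, np.ones(cfg.window), mode="valid")
    counts = np.convolve(np.pad(np.ones_like(x), half, mode="constant"), np.ones(cfg.window), mode="valid")
    return sums / counts


def smooth_matrix(matrix: pd.DataFrame, config: SmoothingConfig | None = None) -> pd.DataFrame:
    """Apply moving_average to every gene row of an expression matrix."""
    out = matrix.copy()
    out.loc[:, :] = np.vstack([moving_average(row, config) for row in matrix.to_numpy(dtype=float)])
    return out


def filter_uninformative_genes(
    matrix: pd.DataFrame, min_std: float = 0.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop genes with temporal standard deviation <= min_std.

    Returns (filtered matrix, removal report). The report has one row per
    removed gene with its standard deviation and the reason. Removing every
    gene raises a warning but still returns the (empty) result explicitly.
    """
    if matrix.empty:
        raise ValueError("expression matrix is empty")
    stds = matrix.std(axis=1, ddof=0)
    removed_mask = stds <= min_std
    report = pd.DataFrame(
        {
            "gene": matrix.index[removed_mask],
            "std": stds[removed_mask].to_numpy(),
            "reason": [
                "constant expression" if s == 0 else f"std <= {min_std}"
                for s in stds[removed_mask]
            ],
        }
    )
    kept = matrix.loc[~removed_mask]
    if kept.empty:
        warnings.warn(
            "all genes removed by the variability filter; result is empty",
            UserWarning,
            stacklevel=2,
        )
    return kept, report
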