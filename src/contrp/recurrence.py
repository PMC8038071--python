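"""Continuous recurrence plots (Cont-RPs) via time-delay embedding.

A scalar series x of length N is embedded into M = N - (m-1)*tau phase-space
vectors v_i = (x[i], x[i+tau], ..., x[i+(m-1)tau]); the Cont-RP is the full
M x M matrix of Euclidean distances ||v_i - v_j||, kept continuous — no
threshold, no binarization.  Default embedding dimension m=3 and delay tau=2
samples (0.125 s at 16 Hz).

At 16 Hz this gives a 156x156 plot for a 10-s segment and 476x476 for 30 s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import ConfigError, DataError


@dataclass(frozen=True)
class EmbeddingConfig:
    m: int = 3
    tau: int = 2
    # Feed raw distances to the CNN by default: signals are z-normalized per
    # recording, so distance amplitude is comparable across subjects and is
    # itself the strongest stressed-vs-relaxed cue.  Per-plot min-max
    # rescaling (rescale=True) is available but discards that amplitude.
    rescale: bool = False

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ConfigError(f"embedding dimension must be >= 1, got {self.m}")
        if self.tau < 1:
            raise ConfigError(f"time delay must be >= 1 sample, got {self.tau}")


@dataclass
class ContRP:
    """Square symmetric non-negative distance matrix with zero diagonal."""

    D: np.ndarray
    meta: Any = None

    @property
    def side(self) -> int:
        return self.D.shape[0]


def embed(x: np.ndarray, cfg: EmbeddingConfig) -> np.ndarray:
    """Time-delay embedding: (M, m) matrix of phase-space vectors."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    span = (cfg.m - 1) * cfg.tau
    if n <= span:
        raise DataError(f"need more than (m-1)*tau={span} samples, got {n}")
    m_rows = n - span
    cols = [x[k * cfg.tau: k * cfg.tau + m_rows] for k in range(cfg.m)]
    return np.stack(cols, axis=1)


def cont_rp(x: np.ndarray, cfg: EmbeddingConfig = EmbeddingConfig(), meta: Any = None) -> ContRP:
    """Continuous recurrence plot: pairwise Euclidean distances of embedded states."""
    v = embed(x, cfg)
    D = squareform(pdist(v, metric="euclidean"))
    return ContRP(D, meta=meta)


def rp_to_image(rp: ContRP, rescale: bool = True) -> np.ndarray:
    """Condition a Cont-RP for the CNN: min-max rescale into [0, 1].

    An all-zero plot (constant input signal) maps to all zeros.  With
    ``rescale=False`` the raw distances are returned unchanged.
    """
    D = rp.D
    if not rescale:
        return D.copy()
    lo, hi = D.min(), D.max()
    if hi - lo <= 0:
        return np.zeros_like(D)
    return (D - lo) / (hi - lo)
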