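"""Multiscale entropy (MSE) of pulse signals.

MSE quantifies the complexity of a time series by evaluating sample entropy
on successively coarse-grained copies: at scale s the series is replaced by
block averages over non-overlapping windows of s consecutive points,

    y_j = (1/s) * sum_{i=(j-1)s+1}^{js} x_i,   j = 1 .. floor(N/s),

and SampEn(m, r) of each coarse-grained series is reported. Sample entropy
is -ln(A/B), where B counts pairs of m-length templates within Chebyshev
distance r, A the same for (m+1)-length templates, self-matches excluded.

Defaults follow the Costa convention: m = 2, r = 0.15 x the standard
deviation of the original (scale-1) series, held fixed across scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import KDTree

__all__ = ["MSEConfig", "coarse_grain", "sample_entropy", "mse_profile"]


@dataclass(frozen=True)
class MSEConfig:
    """Parameters of the MSE profile.

    ``r`` is a fraction of the original series' standard deviation; the
    absolute tolerance is computed once at scale 1 and reused at every
    scale, so scales are compared on a common amplitude criterion.
    """

    max_scale: int = 5
    m: int = 2
    r: float = 0.15

    def __post_init__(self) -> None:
        if self.max_scale < 1 or self.m < 1 or self.r <= 0:
            raise ValueError("require max_scale >= 1, m >= 1, r > 0")


def coarse_grain(x: np.ndarray, s: int) -> np.ndarray:
    """Block-average ``x`` over non-overlapping windows of length ``s``.

    Output length is floor(N/s); trailing remainder samples are discarded.
    """
    x = np.asarray(x, dtype=float)
    if s < 1:
        raise ValueError("scale must be >= 1")
    n = x.size
    if n < s:
        raise ValueError(f"series of length {n} cannot be coarse-grained at scale {s}")
    m = n // s
    return x[: m * s].reshape(m, s).mean(axis=1)


def _embed(y: np.ndarray, m: int) -> np.ndarray:
    """All length-m template vectors of y as rows."""
    n = y.size - m + 1
    return np.lib.stride_tricks.sliding_window_view(y, m)[:n]


def _pair_count(templates: np.ndarray, r: float) -> int:
    """Number of unordered template pairs (i != j) within Chebyshev r."""
    tree = KDTree(templates, metric="chebyshev")
    counts = tree.query_radius(templates, r, count_only=True)
    return int((counts.sum() - templates.shape[0]) // 2)


def sample_entropy(y: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """SampEn(m, r) of a series, with r in absolute amplitude units.

    Follows the standard convention: both template lengths use the same
    N - m vectors, Chebyshev distance, self-matches excluded. Returns NaN
    (undefined) when either count is zero — a constant-free marker rather
    than an arbitrary cap.
    """
    y = np.asarray(y, dtype=float)
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    n = y.size
    if n <= m + 1:
        raise ValueError(f"series of length {n} too short for m={m}")
    xm = _embed(y, m)[: n - m]      # N - m templates of length m
    xm1 = _embed(y, m + 1)          # N - m templates of length m + 1
    b = _pair_count(xm, r)
    if b == 0:
        return float("nan")
    a = _pair_count(xm1, r)
    if a == 0:
        return float("nan")
    return float(-np.log(a / b))


def mse_profile(x: np.ndarray, cfg: MSEConfig = MSEConfig()) -> dict[str, float]:
    """MSE_1..MSE_{max_scale} of a signal.

    The tolerance is ``cfg.r * sd(x)`` computed once from the original
    series. An undefined entropy at any scale propagates as NaN with a
    warning (subjects with undefined profiles are excluded downstream).
    """
    x = np.asarray(x, dtype=float)
    if x.size // cfg.max_scale <= cfg.m + 1:
        raise ValueError(
            f"series of length {x.size} too short for scale {cfg.max_scale}"
        )
    sd = float(np.std(x))
    if sd == 0:
        raise ValueError("constant signal has no amplitude scale for r")
    r_abs = cfg.r * sd
    out: dict[str, float] = {}
    for s in range(1, cfg.max_scale + 1):
        val = sample_entropy(coarse_grain(x, s), cfg.m, r_abs)
        if np.isnan(val):
            warnings.warn(f"sample entropy undefined at scale {s}", stacklevel=2)
        out[f"MSE_{s}"] = val
    return out
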