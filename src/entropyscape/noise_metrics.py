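"""Epigenetic noise statistics.

Four per-sample / per-segment measures of methylome disorder:

* CV — coefficient of variation of a sample's per-site methylation levels.
* QE — quantization-based entropy: Shannon entropy (bits) of the histogram of
  methylation levels over k equal-width bins.
* MPR complexity — Martin-Plastino-Rosso statistical complexity of the
  genome-position-ordered methylation profile, built on the Bandt-Pompe
  ordinal-pattern distribution (natural-log entropy internally, as is
  conventional for permutation entropy).
* ME — read-level methylation entropy of a segment of b consecutive CpGs:
  Shannon entropy (bits) of the read pattern distribution divided by b.

For b=3 there are 2^3 = 8 possible patterns, so 0 <= ME <= 1; with fewer than
2^b reads the attainable maximum is log2(N)/b, and reported values are NOT
rescaled by that bound.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np

__all__ = [
    "coefficient_of_variation",
    "quantization_entropy",
    "methylation_entropy",
    "methylation_entropy_matrix",
    "segment_methylation_level",
    "segment_methylation_level_matrix",
    "ordinal_pattern_distribution",
    "mpr_complexity",
]


def coefficient_of_variation(betas, ddof: int = 1) -> float:
    """sd/mean of a vector of methylation levels (sample sd by default).

    Returns NaN for a zero mean; a single value has zero sd and returns 0.
    """
    x = np.asarray(betas, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("empty vector")
    mu = x.mean()
    if mu == 0:
        return math.nan
    if x.size == 1:
        return 0.0
    return float(x.std(ddof=ddof) / mu)


def quantization_entropy(betas, k: int = 5) -> float:
    """Shannon entropy (bits) of the k-bin histogram of methylation levels.

    Bin i (1-based) covers ((i-1)/k, i/k]; bin 1 is closed at 0 so that
    exact zeros are counted.  Values are clipped to [0, 1] first (batch
    correction can push them slightly outside).  Empty bins contribute 0.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    x = np.asarray(betas, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("empty vector")
    x = np.clip(x, 0.0, 1.0)
    # ceil(x*k) maps (0, 1] onto bins 1..k with left-open edges; 0 -> bin 1
    bins = np.maximum(np.ceil(x * k).astype(int), 1)
    counts = np.bincount(bins, minlength=k + 1)[1:k + 1]
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def methylation_entropy(pattern_counts, b: int) -> float:
    """ME of one segment: (1/b) * sum_i -(n_i/N) log2(n_i/N); 0*log 0 = 0."""
    n = np.asarray(pattern_counts, dtype=float)
    N = n.sum()
    if N <= 0:
        raise ValueError("pattern counts sum to zero")
    p = n[n > 0] / N
    return float(-(p * np.log2(p)).sum() / b)


def methylation_entropy_matrix(counts: np.ndarray, b: int) -> np.ndarray:
    """Vectorized ME over a (..., 2**b) count array; NaN where N = 0."""
    n = np.asarray(counts, dtype=float)
    N = n.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = n / N
        term = np.where(p > 0, p * np.log2(p), 0.0)
    me = -term.sum(axis=-1) / b
    return np.where(N[..., 0] > 0, me, np.nan)


def segment_methylation_level(pattern_counts, b: int) -> float:
    """Fraction of methylated CpG observations in a segment's reads."""
    n = np.asarray(pattern_counts, dtype=float)
    N = n.sum()
    if N <= 0:
        raise ValueError("pattern counts sum to zero")
    ones = np.array([bin(i).count("1") for i in range(n.size)])
    return float((n * ones).sum() / (N * b))


def segment_methylation_level_matrix(counts: np.ndarray, b: int) -> np.ndarray:
    """Vectorized :func:`segment_methylation_level`; NaN where N = 0."""
    n = np.asarray(counts, dtype=float)
    N = n.sum(axis=-1)
    ones = np.array([bin(i).count("1") for i in range(n.shape[-1])], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lvl = (n * ones).sum(axis=-1) / (N * b)
    return np.where(N > 0, lvl, np.nan)


def _pattern_rank(window: np.ndarray) -> tuple[int, ...]:
    # Bandt-Pompe ordinal pattern; ties broken by temporal order (stable sort)
    return tuple(np.argsort(window, kind="stable"))


def ordinal_pattern_distribution(
    series, embed_dim: int = 4, delay: int = 1
) -> np.ndarray:
    """Relative frequencies of the D! Bandt-Pompe ordinal patterns over all
    length-D windows (spacing ``delay``) of the series."""
    if embed_dim < 2:
        raise ValueError("embed_dim must be >= 2")
    x = np.asarray(series, dtype=float)
    x = x[~np.isnan(x)]
    n_windows = len(x) - (embed_dim - 1) * delay
    if n_windows < 1:
        raise ValueError("series too short for the embedding")
    perm_index = {p: i for i, p in enumerate(permutations(range(embed_dim)))}
    counts = np.zeros(len(perm_index), dtype=np.int64)
    for start in range(n_windows):
        window = x[start:start + embed_dim * delay:delay]
        counts[perm_index[_pattern_rank(window)]] += 1
    return counts / counts.sum()


def mpr_complexity(
    series, embed_dim: int = 4, delay: int = 1
) -> tuple[float, float]:
    """(h_norm, C): normalized permutation entropy and MPR statistical
    complexity of a series.

    h_norm = H(P)/ln(D!) with natural-log Shannon entropy of the ordinal
    pattern distribution P; C = Q_J[P, P_uniform] * h_norm, where Q_J is the
    Jensen-Shannon divergence to the uniform distribution normalized by its
    maximum (attained by a degenerate distribution).
    """
    P = ordinal_pattern_distribution(series, embed_dim=embed_dim, delay=delay)
    M = P.size
    nz = P[P > 0]
    H = float(-(nz * np.log(nz)).sum())
    h_norm = H / math.log(M)
    # Jensen-Shannon divergence to uniform, normalized
    Pe = np.full(M, 1.0 / M)
    mix = 0.5 * (P + Pe)
    S_mix = float(-(mix[mix > 0] * np.log(mix[mix > 0])).sum())
    js = S_mix - 0.5 * H - 0.5 * math.log(M)
    q0 = -0.5 * (
        (M + 1) / M * math.log(M + 1) - 2 * math.log(2 * M) + math.log(M)
    )
    qj = js / q0
    return h_norm, float(qj * h_norm)
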