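"""Inference layer: per-pair OLS slopes over layer_fraction, one-sample and
matched-pairs t-tests, the Fisher z transform, and the color-label shuffle
null for the between-object color-space correlation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, InputDomainError
from .metrics import pairwise_vector_correlation_matrix, rsm_offdiag_vector

__all__ = [
    "SlopeResult",
    "TestResult",
    "ShuffleNullResult",
    "pair_slope",
    "one_sample_t",
    "matched_pairs_t",
    "fisher_z",
    "shuffle_color_null",
    "significance_tier",
]


@dataclass(frozen=True)
class SlopeResult:
    """OLS fit of values against layer_fraction for one object pair."""

    pair_id: tuple | str
    slope: float
    intercept: float
    n_points: int


@dataclass(frozen=True)
class TestResult:
    t: float
    df: int
    p: float  # two-tailed
    test_kind: str  # one_sample | matched_pairs
    tails: int = 2


@dataclass
class ShuffleNullResult:
    layer: str
    n_shuffles: int
    per_shuffle_means: np.ndarray
    seed: int

    @property
    def mean_null(self) -> float:
        return float(self.per_shuffle_means.mean())

    @property
    def se_null(self) -> float:
        return float(self.per_shuffle_means.std(ddof=1) / np.sqrt(self.n_shuffles))


def pair_slope(values, fractions, pair_id="") -> SlopeResult:
    """Ordinary least-squares slope of ``values`` on ``fractions``."""
    y = np.asarray(values, dtype=np.float64)
    x = np.asarray(fractions, dtype=np.float64)
    if y.shape != x.shape or y.size < 2:
        raise InputDomainError("need equal-length value/fraction lists of length >= 2")
    if np.any(np.diff(x) <= 0):
        raise InputDomainError("fractions must be strictly increasing")
    xc = x - x.mean()
    slope = float(xc @ (y - y.mean()) / (xc @ xc))
    intercept = float(y.mean() - slope * x.mean())
    return SlopeResult(pair_id, slope, intercept, y.size)


def one_sample_t(values, mu0: float = 0.0) -> TestResult:
    """Two-tailed one-sample t-test (sample sd, divisor n-1)."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise InputDomainError("need at least 2 values")
    s = v.std(ddof=1)
    if s < 1e-300 or v.var(ddof=1) == 0:
        raise DegenerateInputError("zero sample variance")
    n = v.size
    t = float((v.mean() - mu0) / (s / np.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return TestResult(t=t, df=n - 1, p=p, test_kind="one_sample")


def matched_pairs_t(a, b) -> TestResult:
    """Two-tailed matched-pairs t-test: one-sample test on a - b."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise InputDomainError("matched samples must have equal length")
    res = one_sample_t(a - b, 0.0)
    return TestResult(t=res.t, df=res.df, p=res.p, test_kind="matched_pairs")


def fisher_z(r, clamp: float | None = None):
    """Fisher's z = atanh(r), variance-stabilizing a correlation.

    |r| >= 1 raises unless ``clamp`` is given (e.g. ``1 - 1e-7``), in which
    case r is clipped to [-clamp, clamp] first.
    """
    arr = np.asarray(r, dtype=np.float64)
    if clamp is not None:
        arr = np.clip(arr, -clamp, clamp)
    elif np.any(np.abs(arr) >= 1.0):
        raise InputDomainError("|r| >= 1 has no finite Fisher z (pass clamp=...)")
    out = np.arctanh(arr)
    return float(out) if np.ndim(r) == 0 else out


def significance_tier(p: float) -> str:
    """Asterisk tier mirroring conventional reporting (raw p is always kept)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def shuffle_color_null(
    object_patterns: dict,
    n_shuffles: int = 100,
    seed: int = 0,
    layer: str = "",
) -> ShuffleNullResult:
    """Color-label shuffle null for the between-object color-space
    correlation.

    Per shuffle, an independent random permutation of the color labels is
    applied within each object (equivalently: rows/columns of its prebuilt
    color RSM are permuted), color-space vectors are rebuilt, and the mean
    pairwise between-object correlation is recorded. Under shuffling the
    expectation is exactly zero for any true interaction structure.

    Sub-seeds are spawned per (shuffle, object) from the master seed, so any
    single shuffle is reproducible in isolation.

    Parameters
    ----------
    object_patterns : dict
        ``object_id -> (n_colors, n_units)`` raw patterns for one layer.
    """
    if len(object_patterns) < 2:
        raise InputDomainError("need >= 2 objects")
    objects = list(object_patterns)
    rsms = {
        obj: np.corrcoef(np.asarray(p, dtype=np.float64))
        for obj, p in object_patterns.items()
    }
    n_colors = next(iter(rsms.values())).shape[0]

    means = np.empty(n_shuffles)
    for s in range(n_shuffles):
        vectors = []
        for j, obj in enumerate(objects):
            rng = np.random.default_rng(np.random.SeedSequence([seed, s, j]))
            perm = rng.permutation(n_colors)
            shuffled = rsms[obj][np.ix_(perm, perm)]
            vectors.append(rsm_offdiag_vector(shuffled))
        sim = pairwise_vector_correlation_matrix(np.stack(vectors), objects)
        means[s] = sim.mean_offdiag
    return ShuffleNullResult(
        layer=layer, n_shuffles=n_shuffles, per_shuffle_means=means, seed=seed
    )
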