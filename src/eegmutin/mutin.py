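"""Histogram entropy, Kullback-Leibler divergence, mutual information, and
greedy discriminant channel selection.

Channel amplitude distributions are estimated with equal-width histograms
(default 64 bins per channel).  Mutual information between two channels is
the KL divergence of their joint histogram against the product of the
marginals, in nats.  Selection seeds with the channel pair of maximal
mutual information and greedily appends the channel maximizing its
aggregate information with the already-selected set, one channel per
iteration, until the target size is reached.  All subjects' segments are
pooled for the estimates, so the selected subset is representative of
every subject.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np

from .dataset import SegmentSet

_ATOL = 1e-12


class SupportError(ValueError):
    """KLD undefined: P has mass where Q has none."""


@dataclasses.dataclass
class ChannelDistribution:
    """Histogram estimate of one channel's amplitude distribution."""

    bin_edges: np.ndarray       # (n_bins + 1,), monotone
    probabilities: np.ndarray   # (n_bins,), sums to 1
    degenerate: bool = False    # constant input: all mass in one bin

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.probabilities) != len(self.bin_edges) - 1:
            raise ValueError("probabilities length must be len(bin_edges) - 1")
        if np.any(self.probabilities < -_ATOL):
            raise ValueError("negative probability mass")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {self.probabilities.sum()}")


@dataclasses.dataclass
class JointDistribution:
    """Joint histogram of two channels with its marginals."""

    joint: np.ndarray                   # (n_i, n_j), sums to 1
    marginal_i: ChannelDistribution
    marginal_j: ChannelDistribution

    def __post_init__(self) -> None:
        self.joint = np.asarray(self.joint, dtype=float)
        if abs(self.joint.sum() - 1.0) > 1e-9:
            raise ValueError(f"joint sums to {self.joint.sum()}")
        if not np.allclose(self.joint.sum(axis=1),
                           self.marginal_i.probabilities, atol=1e-9):
            raise ValueError("row sums do not reproduce marginal_i")
        if not np.allclose(self.joint.sum(axis=0),
                           self.marginal_j.probabilities, atol=1e-9):
            raise ValueError("column sums do not reproduce marginal_j")


@dataclasses.dataclass
class MutInMatrix:
    """Symmetric pairwise mutual-information matrix (nats).

    The diagonal holds per-channel self-entropies H(M_i) — the information a
    channel shares with itself.
    """

    values: np.ndarray
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or len(self.channel_names) != n:
            raise ValueError("matrix must be square and match channel names")

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.values, index=self.channel_names,
                     columns=self.channel_names).to_csv(path)


@dataclasses.dataclass
class SelectionResult:
    """Ordered greedy selection with its per-step criterion trace."""

    channels: list[str]
    criterion: list[float]
    target_size: int

    def to_dict(self) -> dict:
        return {"channels": self.channels, "criterion": self.criterion,
                "target_size": self.target_size}


# ---------------------------------------------------------------------------
# estimation primitives

def discretize(x: np.ndarray, n_bins: int = 64) -> ChannelDistribution:
    """Equal-width histogram distribution over ``[min(x), max(x)]``.

    A constant input yields a degenerate single-occupied-bin distribution
    (flagged, not an error).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty input")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        edges = np.linspace(lo - 0.5, hi + 0.5, n_bins + 1)
        probs = np.zeros(n_bins)
        probs[n_bins // 2] = 1.0
        return ChannelDistribution(edges, probs, degenerate=True)
    counts, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
    return ChannelDistribution(edges, counts / x.size)


def entropy(d: ChannelDistribution) -> float:
    """Shannon entropy -sum p ln p in nats, with 0 ln 0 := 0."""
    p = d.probabilities
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def kld(p: ChannelDistribution, q: ChannelDistribution) -> float:
    """KL divergence D(P || Q) in nats over a common binning.

    Raises :class:`SupportError` where P has mass on a zero-mass Q bin.
    """
    if len(p.probabilities) != len(q.probabilities):
        raise ValueError("distributions must share a binning")
    pp, qq = p.probabilities, q.probabilities
    bad = (pp > 0) & (qq == 0)
    if np.any(bad):
        raise SupportError(
            f"P has mass in {int(bad.sum())} bin(s) where Q has none"
        )
    nz = pp > 0
    return float((pp[nz] * np.log(pp[nz] / qq[nz])).sum())


def mutual_information(joint: JointDistribution) -> float:
    """I(X;Y) = D(P(X,Y) || P(X)P(Y)) in nats.

    Only cells with nonzero joint mass contribute; such cells necessarily
    have nonzero marginals, so the divergence is always defined.
    """
    j = joint.joint
    pi = joint.marginal_i.probabilities
    pj = joint.marginal_j.probabilities
    prod = np.outer(pi, pj)
    nz = j > 0
    return max(0.0, float((j[nz] * np.log(j[nz] / prod[nz])).sum()))


def joint_from_samples(x: np.ndarray, y: np.ndarray,
                       n_bins: int = 64) -> JointDistribution:
    """Joint equal-width histogram of two paired sample vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must be paired (equal length)")
    counts, xe, ye = np.histogram2d(x, y, bins=n_bins)
    j = counts / x.size
    return JointDistribution(
        joint=j,
        marginal_i=ChannelDistribution(xe, j.sum(axis=1)),
        marginal_j=ChannelDistribution(ye, j.sum(axis=0)),
    )


# ---------------------------------------------------------------------------
# pairwise matrix

def pairwise_mutin_matrix(ds: SegmentSet, n_bins: int = 64,
                          max_samples: int | None = None,
                          seed: int = 0) -> MutInMatrix:
    """Mutual information between every channel pair, all subjects pooled.

    Each channel's sample vector is its amplitude across all segments and
    time points concatenated.  ``max_samples`` caps the pooled sample count
    (deterministic subsample) to bound the cost of the
    ``n_channels * (n_channels - 1) / 2`` joint histograms.
    """
    if ds.n_channels < 2:
        raise ValueError("need at least 2 channels")
    if ds.n_segments == 0:
        raise ValueError("empty dataset")
    n_ch = ds.n_channels
    pooled = ds.data.transpose(1, 0, 2).reshape(n_ch, -1)
    n = pooled.shape[1]
    if max_samples is not None and n > max_samples:
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 9973])
        idx = rng.choice(n, size=max_samples, replace=False)
        idx.sort()
        pooled = pooled[:, idx]
        n = max_samples

    # digitize each channel once into [0, n_bins)
    codes = np.empty((n_ch, n), dtype=np.int32)
    marg = np.empty((n_ch, n_bins))
    for c in range(n_ch):
        x = pooled[c].astype(float)
        lo, hi = float(x.min()), float(x.max())
        if lo == hi:
            codes[c] = n_bins // 2
        else:
            scaled = (x - lo) * (n_bins / (hi - lo))
            codes[c] = np.clip(scaled.astype(np.int32), 0, n_bins - 1)
        marg[c] = np.bincount(codes[c], minlength=n_bins) / n

    with np.errstate(divide="ignore", invalid="ignore"):
        logm = np.where(marg > 0, np.log(marg), 0.0)
    h = np.array([-(marg[c] * logm[c]).sum() for c in range(n_ch)])

    values = np.zeros((n_ch, n_ch))
    np.fill_diagonal(values, h)
    for i in range(n_ch):
        base = codes[i] * n_bins
        for j in range(i + 1, n_ch):
            counts = np.bincount(base + codes[j], minlength=n_bins * n_bins)
            pj = counts.reshape(n_bins, n_bins) / n
            nz = pj > 0
            prod = np.outer(marg[i], marg[j])
            mi = float((pj[nz] * np.log(pj[nz] / prod[nz])).sum())
            values[i, j] = values[j, i] = max(0.0, mi)
    return MutInMatrix(values, list(ds.channel_names))


# ---------------------------------------------------------------------------
# greedy selection

Aggregation = Literal["sum", "mean", "max"]


def select_channels(m: MutInMatrix, target_size: int,
                    aggregation: Aggregation = "sum") -> SelectionResult:
    """Greedy discriminant channel selection.

    Seeds with the pair ``(i, j)`` of maximal mutual information, then adds
    at each step the unselected channel maximizing the aggregate (default:
    sum) of its pairwise mutual information with the selected set.  Ties
    break toward the lowest channel index.  The recorded criterion value is
    the seed MI for the first two channels and the winning aggregate for
    each subsequent addition.
    """
    n = m.values.shape[0]
    if not 2 <= target_size <= n:
        raise ValueError(f"target_size must be in [2, {n}], got {target_size}")
    off = m.values.copy()
    np.fill_diagonal(off, -np.inf)
    # lexicographically-smallest argmax pair
    best = np.unravel_index(np.argmax(off), off.shape)
    i, j = int(min(best)), int(max(best))
    selected = [i, j]
    criterion = [float(off[i, j])] * 2

    remaining = [k for k in range(n) if k not in selected]
    while len(selected) < target_size:
        scores = m.values[np.ix_(remaining, selected)]
        if aggregation == "sum":
            agg = scores.sum(axis=1)
        elif aggregation == "mean":
            agg = scores.mean(axis=1)
        elif aggregation == "max":
            agg = scores.max(axis=1)
        else:
            raise ValueError(f"unknown aggregation {aggregation!r}")
        k = int(np.argmax(agg))          # first (lowest-index) maximum wins
        criterion.append(float(agg[k]))
        selected.append(remaining.pop(k))

    return SelectionResult(
        channels=[m.channel_names[k] for k in selected],
        criterion=criterion,
        target_size=target_size,
    )
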