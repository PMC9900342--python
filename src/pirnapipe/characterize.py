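"""piRNA sequence signatures.

Length distribution, positional nucleotide bias (1U / 10A), the signed
5'-5' distance probability profile between putative primary and secondary
reads within clusters, and a local-linear tricube LOWESS smoother.

Primary/secondary classification defaults to the standard biogenesis
signatures: a read is *primary* if its first base is T (U in RNA space)
and *secondary* if its tenth base is A and its first base is not T; reads
satisfying neither are excluded.  An alternative abundance-based
classifier can be plugged in via the ``classifier`` argument.

The distance profile deliberately ignores read abundance: per cluster it
is built over unique sequences, each cluster's histogram is normalized to
sum 1 over the window, and clusters are aggregated by unweighted mean, so
the aggregate is a convex combination and sums to 1 as well.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .preprocess import CollapsedRead

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class ClusterRead:
    """A read assigned to one cluster, with its genomic 5' position."""

    sequence: str
    five_prime: int
    strand: str = "+"
    multiplicity: int = 1


@dataclass
class DistanceProfile:
    distances: np.ndarray  # signed, [-window, +window]
    probability: np.ndarray
    smoothed: np.ndarray
    n_clusters_contributing: int

    def argmax_distance(self, smoothed: bool = False) -> int:
        arr = self.smoothed if smoothed else self.probability
        return int(self.distances[int(np.argmax(arr))])


@dataclass(frozen=True)
class LowessConfig:
    span: float = 0.1
    degree: int = 1
    kernel: str = "tricube"
    robustness_iterations: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.span <= 1):
            raise ValueError("span must be in (0, 1]")
        if self.degree != 1 or self.kernel != "tricube" or self.robustness_iterations != 0:
            raise ValueError("only degree-1 tricube with 0 robust iterations is supported")


# ---------------------------------------------------------------------------


def length_distribution(reads: Sequence[CollapsedRead]) -> tuple[dict[int, float], int]:
    """Multiplicity-weighted read length frequencies and the modal length."""
    if not reads:
        raise ValueError("length_distribution requires reads")
    counts: Counter[int] = Counter()
    for read in reads:
        counts[len(read.sequence)] += read.multiplicity
    total = sum(counts.values())
    freqs = {length: c / total for length, c in sorted(counts.items())}
    mode = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    return freqs, mode


def five_prime_bias(
    reads: Sequence[CollapsedRead], n_positions: int = 10, weighted: bool = True
) -> tuple[np.ndarray, float]:
    """Positional nucleotide frequencies over the first ``n_positions`` bases.

    Returns a 4 x n_positions matrix (rows A,C,G,T; columns sum to 1) and
    the position-1 T frequency (the 1U fraction in RNA space).
    """
    if not reads:
        raise ValueError("five_prime_bias requires reads")
    counts = np.zeros((4, n_positions))
    base_idx = {b: i for i, b in enumerate(BASES)}
    for read in reads:
        w = read.multiplicity if weighted else 1
        for j, base in enumerate(read.sequence[:n_positions]):
            if base in base_idx:
                counts[base_idx[base], j] += w
    col_tot = counts.sum(axis=0)
    col_tot[col_tot == 0] = 1.0
    matrix = counts / col_tot
    u1 = float(matrix[base_idx["T"], 0])
    return matrix, u1


def default_classifier(read: ClusterRead) -> Optional[str]:
    """1U -> primary; (not 1U) and 10A -> secondary; otherwise excluded."""
    seq = read.sequence
    if seq[0] == "T":
        return "primary"
    if len(seq) >= 10 and seq[9] == "A":
        return "secondary"
    return None


def classify_primary_secondary(
    reads: Sequence[ClusterRead],
    classifier: Callable[[ClusterRead], Optional[str]] = default_classifier,
) -> tuple[list[ClusterRead], list[ClusterRead]]:
    primary, secondary = [], []
    for read in reads:
        label = classifier(read)
        if label == "primary":
            primary.append(read)
        elif label == "secondary":
            secondary.append(read)
    return primary, secondary


def _cluster_histogram(
    primary: Sequence[ClusterRead],
    secondary: Sequence[ClusterRead],
    window: int,
    normalization: str = "histogram",
) -> Optional[np.ndarray]:
    """Per-cluster histogram over signed 5'-5' distances for unique sequences.

    For every same-strand (primary, secondary) pair the signed distance is
    the secondary 5' position minus the primary 5' position, measured in
    the reads' transcription direction (sign flips on the minus strand).

    ``normalization="histogram"`` (default) scales the histogram to sum 1
    over the window; ``"diverse_pirnas"`` divides by the number of diverse
    (unique-sequence) reads associated with the cluster instead.
    """
    uniq_primary = {r.sequence: r for r in primary}.values()
    uniq_secondary = {r.sequence: r for r in secondary}.values()
    hist = np.zeros(2 * window + 1)
    n_pairs = 0
    for p in uniq_primary:
        for s in uniq_secondary:
            if p.strand != s.strand:
                continue
            d = s.five_prime - p.five_prime
            if p.strand == "-":
                d = -d
            if abs(d) <= window:
                hist[d + window] += 1
                n_pairs += 1
    if n_pairs == 0:
        return None
    if normalization == "diverse_pirnas":
        return hist / (len(uniq_primary) + len(uniq_secondary))
    if normalization != "histogram":
        raise ValueError(f"unknown normalization {normalization!r}")
    return hist / hist.sum()


def distance_probability(
    clusters: dict[str, Sequence[ClusterRead]],
    window: int = 200,
    lowess_span: float = 0.1,
    classifier: Callable[[ClusterRead], Optional[str]] = default_classifier,
    normalization: str = "histogram",
) -> DistanceProfile:
    """Aggregate 5'-5' distance probability profile across clusters."""
    histograms = []
    for cid, reads in sorted(clusters.items()):
        primary, secondary = classify_primary_secondary(reads, classifier)
        if not primary or not secondary:
            continue
        hist = _cluster_histogram(primary, secondary, window, normalization)
        if hist is not None:
            histograms.append(hist)
    distances = np.arange(-window, window + 1)
    if not histograms:
        logger.warning("distance_probability: no qualifying primary/secondary pairs")
        empty = np.zeros(2 * window + 1)
        return DistanceProfile(distances, empty, empty.copy(), 0)
    probability = np.mean(histograms, axis=0)
    smoothed = lowess_fit(distances.astype(float), probability, LowessConfig(span=lowess_span))
    return DistanceProfile(distances, probability, smoothed, len(histograms))


# ---------------------------------------------------------------------------
# LOWESS


def lowess_fit(
    x: Sequence[float], y: Sequence[float], config: LowessConfig = LowessConfig()
) -> np.ndarray:
    """Local linear regression with tricube weights at each input point.

    At each x_i a degree-1 weighted least squares is fit over the
    ``ceil(span * n)`` nearest neighbors with weights
    ``(1 - (d/dmax)^3)^3``; the fitted value at x_i is returned.  Inputs
    need not be sorted; outputs align with input order.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("lowess requires at least 3 points")
    q = math.ceil(config.span * n)
    if q < 2:
        raise ValueError(f"span {config.span} covers {q} < 2 points; cannot fit a line")
    fitted = np.empty(n)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    for idx in range(n):
        xi = x[idx]
        d = np.abs(xs - xi)
        neighbor_idx = np.argsort(d, kind="stable")[:q]
        dmax = d[neighbor_idx].max()
        if dmax == 0:
            fitted[idx] = ys[neighbor_idx].mean()
            continue
        w = (1 - (d[neighbor_idx] / dmax) ** 3) ** 3
        xw, yw = xs[neighbor_idx], ys[neighbor_idx]
        sw = w.sum()
        xbar = (w * xw).sum() / sw
        ybar = (w * yw).sum() / sw
        sxx = (w * (xw - xbar) ** 2).sum()
        if sxx <= 0:
            fitted[idx] = ybar
            continue
        beta = (w * (xw - xbar) * (yw - ybar)).sum() / sxx
        fitted[idx] = ybar + beta * (xi - xbar)
    return fitted
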