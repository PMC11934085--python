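"""Pairwise association measures between OTU index vectors.

Five measures form the ensemble: Pearson and Spearman correlation,
Bray-Curtis and (symmetrized) Kullback-Leibler dissimilarity, and plug-in
mutual information on equal-frequency discretizations.  Correlations are
signed (positive = co-presence, negative = mutual exclusion);
dissimilarities and mutual information are unsigned at the scoring stage
and acquire a direction only when a tail is selected.

Scalar entry points (:func:`pearson` ...) serve single pairs; the
``*_rows`` helpers score many vector pairs at once and back the
permutation/bootstrap machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .index import IndexTable

__all__ = [
    "METRICS",
    "SIGNED_METRICS",
    "DISSIMILARITY_METRICS",
    "UndefinedScoreError",
    "PairScore",
    "MetricParams",
    "pearson",
    "spearman",
    "bray_curtis",
    "kld",
    "mutual_information",
    "score_all_pairs",
]

METRICS: tuple[str, ...] = (
    "pearson",
    "spearman",
    "bray_curtis",
    "kld",
    "mutual_information",
)
#: Metrics whose score sign carries the co-presence/exclusion direction.
SIGNED_METRICS = frozenset({"pearson", "spearman"})
#: Metrics where LOW values mean similarity (co-presence).
DISSIMILARITY_METRICS = frozenset({"bray_curtis", "kld"})


class UndefinedScoreError(ValueError):
    """A measure is undefined on this input (e.g. a constant vector)."""


@dataclass(frozen=True)
class MetricParams:
    """Tunables shared by the ensemble.

    ``mi_bins`` — number of equal-frequency bins for mutual information;
    4 keeps at least ~5 expected observations per bin at the survey's
    20-60 sample subsets.  ``kld_pseudocount`` — additive offset that
    makes the KL dissimilarity finite on vectors with zeros.
    """

    mi_bins: int = 4
    kld_pseudocount: float = 1e-8


@dataclass(frozen=True)
class PairScore:
    otu_a: str
    otu_b: str
    metric: str
    score: float
    direction: str  # "copresence" | "exclusion" | "unsigned"


def _as_vec(x: Sequence[float]) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-D vector")
    return v


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; undefined if either vector is constant."""
    xv, yv = _as_vec(x), _as_vec(y)
    if xv.shape != yv.shape or xv.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise UndefinedScoreError("constant vector: Pearson undefined")
    return float(stats.pearsonr(xv, yv).statistic)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    xv, yv = _as_vec(x), _as_vec(y)
    if xv.shape != yv.shape or xv.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise UndefinedScoreError("constant vector: Spearman undefined")
    return float(stats.spearmanr(xv, yv).statistic)


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) on non-negative vectors."""
    xv, yv = _as_vec(x), _as_vec(y)
    if (xv < 0).any() or (yv < 0).any():
        raise ValueError("Bray-Curtis needs non-negative vectors")
    denom = float((xv + yv).sum())
    if denom == 0:
        raise UndefinedScoreError("both vectors all-zero: Bray-Curtis undefined")
    return float(np.abs(xv - yv).sum() / denom)


def kld(x: Sequence[float], y: Sequence[float], pseudocount: float = 1e-8) -> float:
    """Symmetrized (Jeffreys) Kullback-Leibler divergence, natural-log units.

    Both vectors are shifted by ``pseudocount`` and renormalized to sum 1,
    which keeps the divergence finite in the presence of zeros.
    """
    xv, yv = _as_vec(x), _as_vec(y)
    if (xv < 0).any() or (yv < 0).any():
        raise ValueError("KL dissimilarity needs non-negative vectors")
    p = xv + pseudocount
    q = yv + pseudocount
    if p.sum() == 0 or q.sum() == 0:
        raise UndefinedScoreError("all-zero vector with zero pseudocount")
    p = p / p.sum()
    q = q / q.sum()
    return float(np.sum((p - q) * (np.log(p) - np.log(q))))


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each value to one of ``n_bins`` equal-frequency bins.

    Sorting is stable on sample order, so the assignment is
    deterministic; bins hold ⌈n/B⌉ or ⌊n/B⌋ points when values are
    distinct.  Exactly equal values always share a bin (the bin of the
    first member of their tied run), so a constant vector occupies a
    single bin and carries no information.
    """
    x2 = np.atleast_2d(x)
    k, n = x2.shape
    order = np.argsort(x2, axis=-1, kind="stable")
    xs = np.take_along_axis(x2, order, axis=-1)
    pos = np.broadcast_to((np.arange(n) * n_bins) // n, (k, n))
    # index of the first element of each tied run, forward-propagated
    new_run = np.ones((k, n), dtype=bool)
    new_run[:, 1:] = xs[:, 1:] != xs[:, :-1]
    start = np.where(new_run, np.arange(n), 0)
    start = np.maximum.accumulate(start, axis=-1)
    bins_sorted = np.take_along_axis(pos, start, axis=-1)
    bins = np.empty_like(order)
    np.put_along_axis(bins, order, bins_sorted, axis=-1)
    return bins.reshape(np.shape(x))


def mutual_information(
    x: Sequence[float], y: Sequence[float], n_bins: int = 4
) -> float:
    """Plug-in mutual information in bits on equal-frequency discretizations."""
    xv, yv = _as_vec(x), _as_vec(y)
    if xv.shape != yv.shape:
        raise ValueError("vectors must have equal length")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n_bins > xv.size:
        raise ValueError("n_bins exceeds vector length")
    return float(_mi_rows(xv[None, :], yv[None, :], n_bins)[0])


# ---------------------------------------------------------------------------
# Vectorized row-wise scorers: X, Y are (k, n); return length-k score arrays.
# Undefined scores come back as NaN rather than raising.
# ---------------------------------------------------------------------------

def _pearson_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc * Xc).sum(axis=1))
    sy = np.sqrt((Yc * Yc).sum(axis=1))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * Yc).sum(axis=1) / denom
    r = np.where(denom > 0, r, np.nan)
    return np.clip(r, -1.0, 1.0)


def _spearman_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    rx = stats.rankdata(X, axis=1)
    ry = stats.rankdata(Y, axis=1)
    return _pearson_rows(rx, ry)


def _bray_curtis_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    denom = (X + Y).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.abs(X - Y).sum(axis=1) / denom
    return np.where(denom > 0, d, np.nan)


def _kld_rows(X: np.ndarray, Y: np.ndarray, pseudocount: float) -> np.ndarray:
    P = X + pseudocount
    Q = Y + pseudocount
    P = P / P.sum(axis=1, keepdims=True)
    Q = Q / Q.sum(axis=1, keepdims=True)
    return np.sum((P - Q) * (np.log(P) - np.log(Q)), axis=1)


def _mi_rows(X: np.ndarray, Y: np.ndarray, n_bins: int) -> np.ndarray:
    k, n = X.shape
    bx = _equal_frequency_bins(X, n_bins)
    by = _equal_frequency_bins(Y, n_bins)
    codes = (np.arange(k)[:, None] * n_bins * n_bins + bx * n_bins + by).ravel()
    joint = np.bincount(codes, minlength=k * n_bins * n_bins).reshape(k, n_bins, n_bins)
    pj = joint / n
    px = pj.sum(axis=2, keepdims=True)
    py = pj.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = pj * np.log2(pj / (px * py))
    return np.nansum(terms, axis=(1, 2))


def _score_rows(
    metric: str, X: np.ndarray, Y: np.ndarray, params: MetricParams
) -> np.ndarray:
    if metric == "pearson":
        return _pearson_rows(X, Y)
    if metric == "spearman":
        return _spearman_rows(X, Y)
    if metric == "bray_curtis":
        return _bray_curtis_rows(X, Y)
    if metric == "kld":
        return _kld_rows(X, Y, params.kld_pseudocount)
    if metric == "mutual_information":
        return _mi_rows(X, Y, params.mi_bins)
    raise ValueError(f"unknown metric {metric!r}")


def _score_direction(metric: str, score: float) -> str:
    if metric in SIGNED_METRICS:
        return "copresence" if score >= 0 else "exclusion"
    return "unsigned"


def score_all_pairs(
    index: IndexTable,
    metrics: Iterable[str] = METRICS,
    params: MetricParams | None = None,
) -> tuple[list[PairScore], list[tuple[str, str, str]]]:
    """Score every unordered OTU pair with every requested metric.

    Returns ``(scores, skipped)``: pairs on which a metric is undefined
    (constant vector, empty support) are skipped for that metric and
    recorded as ``(otu_a, otu_b, metric)`` provenance entries.  Pairs are
    emitted in canonical lexicographic order, metrics in the order given.
    """
    params = params or MetricParams()
    metrics = tuple(metrics)
    for m in metrics:
        if m not in METRICS:
            raise ValueError(f"unknown metric {m!r}")
    otus = index.otu_ids
    if len(otus) < 2:
        raise ValueError("need at least 2 OTUs to score pairs")
    V = index.values.to_numpy(dtype=float)
    order = np.argsort(np.asarray(otus, dtype=object))
    pairs: list[tuple[int, int]] = []
    for ai in range(len(order)):
        for bi in range(ai + 1, len(order)):
            pairs.append((order[ai], order[bi]))
    ia = np.fromiter((p[0] for p in pairs), dtype=int)
    ib = np.fromiter((p[1] for p in pairs), dtype=int)
    X, Y = V[ia], V[ib]
    scores: list[PairScore] = []
    skipped: list[tuple[str, str, str]] = []
    for metric in metrics:
        vals = _score_rows(metric, X, Y, params)
        for (i, j), s in zip(pairs, vals):
            a, b = otus[i], otus[j]
            if np.isnan(s):
                skipped.append((a, b, metric))
            else:
                scores.append(
                    PairScore(a, b, metric, float(s), _score_direction(metric, float(s)))
                )
    return scores, skipped


def write_pair_scores(scores: Sequence[PairScore], path) -> None:
    """Long-format TSV: otu_a, otu_b, metric, score, direction."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("otu_a\totu_b\tmetric\tscore\tdirection\n")
        for s in scores:
            fh.write(f"{s.otu_a}\t{s.otu_b}\t{s.metric}\t{s.score:.10g}\t{s.direction}\n")
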