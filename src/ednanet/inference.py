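"""Significance machinery for the co-occurrence network.

The ensemble design is two-phase.  Phase one is cheap screening: every
unordered OTU pair is scored with the five association measures, the
extreme tails of each measure's score distribution are marked as
candidate edges, and only pairs supported by at least ``min_support``
measures with a unanimous sign survive.  Phase two prices the survivors:
a permutation null with compositional renormalization (the ReBoot idea)
yields per-measure p-values, bootstrap confidence intervals gate edge
stability, dependent p-values are merged with Brown's method and the
merged values are corrected with Benjamini-Hochberg.

Compositional renormalization means each permutation is not a plain
shuffle: after permuting the two focal OTU rows, every sample's
composition is re-closed over the full community (each affected sample's
values are rescaled so the sample total is preserved), which reproduces
the spurious-correlation structure that closure imposes on the null.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .index import IndexTable
from .metrics import (
    METRICS,
    SIGNED_METRICS,
    DISSIMILARITY_METRICS,
    MetricParams,
    PairScore,
    UndefinedScoreError,
    _score_rows,
    score_all_pairs,
)

__all__ = [
    "InferenceConfig",
    "EdgeCandidate",
    "EdgeResult",
    "CoocNetwork",
    "select_tails",
    "consensus_filter",
    "reboot_null",
    "bootstrap_scores",
    "metric_pvalue",
    "brown_merge",
    "bh_adjust",
    "infer_network",
]


@dataclass(frozen=True)
class InferenceConfig:
    """Full parameterization of a network inference run.

    ``top_k``/``bottom_k`` are the per-metric tail sizes retained as
    candidates (500/500 captures both co-presences and exclusions);
    ``n_perm``/``n_boot`` are the permutation-null and bootstrap iteration
    counts; edges with BH-adjusted ``q > q_threshold`` are discarded.
    """

    metrics: tuple[str, ...] = METRICS
    top_k: int = 500
    bottom_k: int = 500
    min_support: int = 2
    n_perm: int = 100
    n_boot: int = 100
    q_threshold: float = 0.05
    mi_bins: int = 4
    kld_pseudocount: float = 1e-8
    seed: int = 0

    @property
    def metric_params(self) -> MetricParams:
        return MetricParams(mi_bins=self.mi_bins, kld_pseudocount=self.kld_pseudocount)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["metrics"] = list(self.metrics)
        return d


@dataclass
class EdgeCandidate:
    """A pair marked by tail selection, with per-metric provenance."""

    otu_a: str
    otu_b: str
    metric_scores: dict[str, float] = field(default_factory=dict)
    metric_directions: dict[str, str] = field(default_factory=dict)  # selecting metrics only
    sign: str | None = None  # set by consensus_filter

    @property
    def support(self) -> int:
        return len(self.metric_directions)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.otu_a, self.otu_b)


@dataclass
class EdgeResult:
    otu_a: str
    otu_b: str
    sign: str  # "copresence" | "exclusion"
    support: int
    metric_scores: dict[str, float]
    metric_p: dict[str, float]
    stability: dict[str, tuple[float, float, bool]]  # (ci_lo, ci_hi, passed)
    merged_p: float
    q_value: float = float("nan")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.otu_a, self.otu_b)


@dataclass
class CoocNetwork:
    """Significant signed co-occurrences over a community of OTUs."""

    nodes: list[str]
    edges: list[EdgeResult]
    config: InferenceConfig
    provenance: dict = field(default_factory=dict)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(
                e.otu_a,
                e.otu_b,
                sign=e.sign,
                support=e.support,
                merged_p=e.merged_p,
                q_value=e.q_value,
            )
        return g

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {e.pair for e in self.edges}

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for e in sorted(self.edges, key=lambda e: e.pair):
            row: dict = {
                "otu_a": e.otu_a,
                "otu_b": e.otu_b,
                "sign": e.sign,
                "support": e.support,
            }
            for m in self.config.metrics:
                row[f"score_{m}"] = e.metric_scores.get(m, np.nan)
                row[f"p_{m}"] = e.metric_p.get(m, np.nan)
            row["merged_p"] = e.merged_p
            row["q_value"] = e.q_value
            rows.append(row)
        cols = ["otu_a", "otu_b", "sign", "support"]
        for m in self.config.metrics:
            cols += [f"score_{m}", f"p_{m}"]
        cols += ["merged_p", "q_value"]
        return pd.DataFrame(rows, columns=cols)

    def write_edge_table(self, path: str | Path) -> None:
        self.edge_table().to_csv(path, sep="\t", index=False, float_format="%.8g")

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph(), path)


# ---------------------------------------------------------------------------
# Phase one: tail selection and consensus
# ---------------------------------------------------------------------------

def _tail_sizes(n: int, top_k: int, bottom_k: int) -> tuple[int, int]:
    """Disjoint top/bottom tail sizes; when the pool is smaller than the
    combined request, every pair is selected and the pool is split
    proportionally between the tails."""
    top_n = min(top_k, n)
    bottom_n = min(bottom_k, n)
    if top_n + bottom_n > n:
        total = top_k + bottom_k
        bottom_n = (n * bottom_k) // total if total else 0
        top_n = n - bottom_n
    return top_n, bottom_n


def select_tails(
    scores: Sequence[PairScore], top_k: int = 500, bottom_k: int = 500
) -> list[EdgeCandidate]:
    """Mark the per-metric extreme tails as candidate edges.

    Direction conventions: correlations sign by the score's sign
    regardless of tail; dissimilarities map the bottom tail (similar
    profiles) to co-presence and the top tail to exclusion; mutual
    information selects only its top tail and contributes no direction.
    Ties at the tail boundary go to the lexicographically smaller pair.
    """
    if top_k < 0 or bottom_k < 0:
        raise ValueError("tail sizes must be non-negative")
    by_metric: dict[str, list[PairScore]] = {}
    for s in scores:
        by_metric.setdefault(s.metric, []).append(s)
    cands: dict[tuple[str, str], EdgeCandidate] = {}

    def cand(s: PairScore) -> EdgeCandidate:
        key = (s.otu_a, s.otu_b)
        if key not in cands:
            cands[key] = EdgeCandidate(s.otu_a, s.otu_b)
        c = cands[key]
        c.metric_scores[s.metric] = s.score
        return c

    for metric, ms in by_metric.items():
        n = len(ms)
        if metric == "mutual_information":
            top_n, bottom_n = min(top_k, n), 0
        else:
            top_n, bottom_n = _tail_sizes(n, top_k, bottom_k)
        bottom = sorted(ms, key=lambda s: (s.score, (s.otu_a, s.otu_b)))[:bottom_n]
        top = sorted(ms, key=lambda s: (-s.score, (s.otu_a, s.otu_b)))[:top_n]
        for s in bottom:
            c = cand(s)
            if metric in SIGNED_METRICS:
                c.metric_directions[metric] = "copresence" if s.score >= 0 else "exclusion"
            elif metric in DISSIMILARITY_METRICS:
                c.metric_directions[metric] = "copresence"
        for s in top:
            c = cand(s)
            if metric in SIGNED_METRICS:
                c.metric_directions[metric] = "copresence" if s.score >= 0 else "exclusion"
            elif metric in DISSIMILARITY_METRICS:
                c.metric_directions[metric] = "exclusion"
            else:  # mutual information: support without a direction
                c.metric_directions[metric] = "unsigned"
    return [cands[k] for k in sorted(cands)]


def consensus_filter(
    candidates: Sequence[EdgeCandidate], min_support: int = 2
) -> tuple[list[EdgeCandidate], dict[str, int]]:
    """Keep candidates backed by >= ``min_support`` metrics whose signed
    directions agree.

    Mutual information counts toward support but carries no sign; a pair
    must be signed by at least one correlation or dissimilarity tail, and
    pairs whose signed metrics disagree are dropped as conflicting.
    Returns the kept candidates (with ``sign`` set) and drop counters.
    """
    kept: list[EdgeCandidate] = []
    dropped = {"low_support": 0, "conflicting_sign": 0, "unsigned_only": 0}
    for c in candidates:
        if c.support < min_support:
            dropped["low_support"] += 1
            continue
        signs = {d for d in c.metric_directions.values() if d != "unsigned"}
        if not signs:
            dropped["unsigned_only"] += 1
            continue
        if len(signs) > 1:
            dropped["conflicting_sign"] += 1
            continue
        c.sign = signs.pop()
        kept.append(c)
    return kept, dropped


# ---------------------------------------------------------------------------
# Phase two: permutation null, bootstrap, Brown's merge, BH
# ---------------------------------------------------------------------------

def _pair_rng(seed: int, otu_a: str, otu_b: str) -> np.random.Generator:
    """Substream derived from the master seed by a stable hash of the pair,
    so results do not depend on candidate iteration order."""
    key = zlib.crc32(f"{otu_a}\t{otu_b}".encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def _draw_indices(
    rng: np.random.Generator, n: int, n_perm: int, n_boot: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    perm_a = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_b = np.argsort(rng.random((n_perm, n)), axis=1)
    boot = rng.integers(0, n, size=(n_boot, n))
    return perm_a, perm_b, boot


@dataclass(frozen=True)
class _NullBasis:
    """Matrices backing the permutation null for one index table.

    ``V`` carries the index values the observed scores are computed on.
    ``P`` is the abundance-scale matrix used for compositional
    renormalization (the retained proportions when available, else ``V``
    itself), ``S`` its column totals and ``m`` the per-row constants
    mapping renormalized proportions back onto the index scale.
    """

    V: np.ndarray
    P: np.ndarray
    S: np.ndarray
    m: np.ndarray
    proportional: bool  # True when P is a genuine abundance scale


def _null_basis(index: IndexTable) -> _NullBasis:
    V = index.values.to_numpy(dtype=float)
    if index.abundances is not None:
        P = index.abundances.to_numpy(dtype=float)
        S = P.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            prop = np.where(S > 0, P / np.where(S > 0, S, 1.0), 0.0)
        m = prop.max(axis=1)
        m = np.where(m > 0, m, 1.0)
        return _NullBasis(V=V, P=P, S=S, m=m, proportional=True)
    P = V
    S = P.sum(axis=0)
    return _NullBasis(V=V, P=P, S=S, m=np.ones(V.shape[0]), proportional=False)


def _renormalized_rows(
    basis: _NullBasis, ia: int, ib: int,
    perm_a: np.ndarray, perm_b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Permute the two focal rows and recompute each sample's
    compositional normalization over the full community.

    With the abundance scale available, the permuted values are divided
    by the destination sample's NEW total, so the null inherits the
    shared-denominator dependence that closure induces between any two
    taxa; the index row-scaling constants are NOT recomputed.  Without
    it, the permuted index rows are rescaled so each sample total is
    preserved (a weaker, total-preserving re-closure).
    """
    P, S = basis.P, basis.S
    Xa = P[ia][perm_a]
    Xb = P[ib][perm_b]
    s_new = S[None, :] - P[ia] - P[ib] + Xa + Xb
    with np.errstate(invalid="ignore", divide="ignore"):
        if basis.proportional:
            inv = np.where(s_new > 0, 1.0 / np.where(s_new > 0, s_new, 1.0), 0.0)
            return (Xa * inv) / basis.m[ia], (Xb * inv) / basis.m[ib]
        scale = np.where(s_new > 0, S[None, :] / s_new, 0.0)
        return Xa * scale, Xb * scale


def _pair_engine(
    basis: _NullBasis,
    ia: int,
    ib: int,
    metrics: Sequence[str],
    n_perm: int,
    n_boot: int,
    rng: np.random.Generator,
    params: MetricParams,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Null and bootstrap score samples for one pair, with the SAME
    permutations shared across metrics (required for Brown alignment)."""
    V = basis.V
    n = V.shape[1]
    perm_a, perm_b, boot = _draw_indices(rng, n, n_perm, n_boot)
    Na, Nb = _renormalized_rows(basis, ia, ib, perm_a, perm_b)
    Ba, Bb = V[ia][boot], V[ib][boot]
    nulls: dict[str, np.ndarray] = {}
    boots: dict[str, np.ndarray] = {}
    for m in metrics:
        nv = _score_rows(m, Na, Nb, params)
        bv = _score_rows(m, Ba, Bb, params)
        for label, arr in (("null", nv), ("boot", bv)):
            bad = np.isnan(arr)
            if bad.any():
                # one resampling pass for degenerate iterations, then fail
                if label == "null":
                    ra, rb, _ = _draw_indices(rng, n, int(bad.sum()), 0)
                    Ra, Rb = _renormalized_rows(basis, ia, ib, ra, rb)
                else:
                    _, _, rb = _draw_indices(rng, n, 0, int(bad.sum()))
                    Ra, Rb = V[ia][rb], V[ib][rb]
                redo = _score_rows(m, Ra, Rb, params)
                if np.isnan(redo).any():
                    raise UndefinedScoreError(
                        f"metric {m} undefined on resampled data for pair "
                        f"({ia}, {ib})"
                    )
                arr[bad] = redo
        nulls[m] = nv
        boots[m] = bv
    return nulls, boots


def reboot_null(
    index: IndexTable,
    otu_a: str,
    otu_b: str,
    metric: str,
    n_perm: int = 100,
    seed: int = 0,
    params: MetricParams | None = None,
) -> np.ndarray:
    """Null score sample for one pair under renormalized permutations."""
    params = params or MetricParams()
    basis = _null_basis(index)
    ia, ib = index.otu_ids.index(otu_a), index.otu_ids.index(otu_b)
    rng = _pair_rng(seed, otu_a, otu_b)
    nulls, _ = _pair_engine(basis, ia, ib, [metric], n_perm, 0, rng, params)
    return nulls[metric]


def bootstrap_scores(
    index: IndexTable,
    otu_a: str,
    otu_b: str,
    metric: str,
    n_boot: int = 100,
    seed: int = 0,
    params: MetricParams | None = None,
) -> np.ndarray:
    """Bootstrap score sample (samples resampled with replacement)."""
    params = params or MetricParams()
    basis = _null_basis(index)
    ia, ib = index.otu_ids.index(otu_a), index.otu_ids.index(otu_b)
    rng = _pair_rng(seed, otu_a, otu_b)
    _, boots = _pair_engine(basis, ia, ib, [metric], 0, n_boot, rng, params)
    return boots[metric]


def metric_pvalue(
    observed: float, null_sample: np.ndarray, boot_sample: np.ndarray
) -> tuple[float, tuple[float, float, bool]]:
    """Gaussian-tail p-value against the permutation null plus a
    bootstrap stability verdict.

    p is the two-sided tail of N(mean, sd) fitted to the null scores;
    the edge is stable iff the null mean falls OUTSIDE the central 95%
    interval of the bootstrap scores.
    """
    null_sample = np.asarray(null_sample, dtype=float)
    boot_sample = np.asarray(boot_sample, dtype=float)
    if null_sample.size == 0 or boot_sample.size == 0:
        raise ValueError("empty null or bootstrap sample")
    mu = float(null_sample.mean())
    sd = float(null_sample.std(ddof=1)) if null_sample.size > 1 else 0.0
    if sd == 0:
        p = 1.0 if observed == mu else 1.0 / (null_sample.size + 1)
    else:
        p = float(2.0 * stats.norm.sf(abs(observed - mu) / sd))
    lo, hi = np.percentile(boot_sample, [2.5, 97.5])
    stable = bool(mu < lo or mu > hi)
    return p, (float(lo), float(hi), stable)


def _null_pvalues(null_sample: np.ndarray) -> np.ndarray:
    """p-values of the null scores themselves under the fitted Gaussian;
    aligned replicates for Brown's empirical variance."""
    mu = null_sample.mean()
    sd = null_sample.std(ddof=1) if null_sample.size > 1 else 0.0
    if sd == 0:
        return np.ones_like(null_sample)
    return 2.0 * stats.norm.sf(np.abs(null_sample - mu) / sd)


def brown_merge(
    pvals: Sequence[float],
    null_pvals: np.ndarray,
    floor: float = 1.0 / 101.0,
) -> float:
    """Brown's method for dependent p-values with empirical variance.

    The Fisher statistic X = -2 sum(ln p_i) has mean 2k under the null;
    its variance is estimated as the empirical variance of X over the
    aligned null p-value replicates (rows = permutations, columns =
    metrics), which captures the inter-metric dependence without a
    parametric correlation model.  The merged p is the upper tail of the
    scaled chi-square c * chi2_f matched to that mean and variance.
    Independence (Var = 4k) recovers Fisher's method exactly.
    """
    p = np.clip(np.asarray(pvals, dtype=float), floor, 1.0)
    k = p.size
    if k == 0:
        raise ValueError("no p-values to merge")
    if k == 1:
        return float(p[0])
    X = float(-2.0 * np.log(p).sum())
    null_pvals = np.clip(np.asarray(null_pvals, dtype=float), floor, 1.0)
    if null_pvals.ndim != 2 or null_pvals.shape[1] != k:
        raise ValueError("null_pvals must be (n_replicates, k)")
    X0 = -2.0 * np.log(null_pvals).sum(axis=1)
    mean0 = 2.0 * k
    var0 = float(X0.var(ddof=1)) if X0.size > 1 else 0.0
    if var0 <= 0:
        var0 = 4.0 * k  # independence fallback
    c = var0 / (2.0 * mean0)
    f = 2.0 * mean0 * mean0 / var0
    return float(stats.chi2.sf(X / c, f))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def infer_network(index: IndexTable, config: InferenceConfig | None = None) -> CoocNetwork:
    """Run the full ensemble inference on a prevalence-filtered index table."""
    config = config or InferenceConfig()
    params = config.metric_params
    scores, skipped = score_all_pairs(index, config.metrics, params)
    candidates = select_tails(scores, config.top_k, config.bottom_k)
    kept, dropped = consensus_filter(candidates, config.min_support)

    basis = _null_basis(index)
    pos = {o: i for i, o in enumerate(index.otu_ids)}
    floor = 1.0 / (config.n_perm + 1)

    surviving: list[EdgeResult] = []
    n_unstable = 0
    for c in sorted(kept, key=lambda c: c.pair):
        metrics_sup = [m for m in config.metrics if m in c.metric_directions]
        rng = _pair_rng(config.seed, c.otu_a, c.otu_b)
        nulls, boots = _pair_engine(
            basis, pos[c.otu_a], pos[c.otu_b], metrics_sup,
            config.n_perm, config.n_boot, rng, params,
        )
        metric_p: dict[str, float] = {}
        stability: dict[str, tuple[float, float, bool]] = {}
        null_p = np.empty((config.n_perm, len(metrics_sup)))
        stable_all = True
        for j, m in enumerate(metrics_sup):
            p, stab = metric_pvalue(c.metric_scores[m], nulls[m], boots[m])
            metric_p[m] = p
            stability[m] = stab
            null_p[:, j] = _null_pvalues(nulls[m])
            stable_all &= stab[2]
        if not stable_all:
            n_unstable += 1
            continue
        merged = brown_merge([metric_p[m] for m in metrics_sup], null_p, floor)
        surviving.append(
            EdgeResult(
                otu_a=c.otu_a,
                otu_b=c.otu_b,
                sign=c.sign or "copresence",
                support=c.support,
                metric_scores=dict(c.metric_scores),
                metric_p=metric_p,
                stability=stability,
                merged_p=merged,
            )
        )

    if surviving:
        q = bh_adjust([e.merged_p for e in surviving])
        for e, qv in zip(surviving, q):
            e.q_value = float(qv)
    edges = [e for e in surviving if e.q_value <= config.q_threshold]
    provenance = {
        "n_pairs_scored": len({(sc.otu_a, sc.otu_b) for sc in scores}),
        "n_metric_skips": len(skipped),
        "n_candidates": len(candidates),
        "n_consensus": len(kept),
        "dropped": dropped,
        "n_unstable": n_unstable,
        "n_tested": len(surviving),
        "seed": config.seed,
    }
    return CoocNetwork(
        nodes=list(index.otu_ids), edges=edges, config=config, provenance=provenance
    )
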