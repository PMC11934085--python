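"""Self-validation benchmarks on synthetic communities.

These routines run the full observation-plus-inference path on
communities with known ground truth and summarize how well the engine
behaves: false-edge rate on independent-OTU (null) communities,
uniformity of the per-metric permutation p-values, and recovery of
planted associations at the emulated survey scale (60 samples,
sequencing depth 1e5, planted strength 0.9).
"""

from __future__ import annotations

from functools import reduce

import numpy as np
from scipy import stats

from .index import IndexTable, ensemble_index, index_from_table
from .inference import (
    InferenceConfig,
    infer_network,
    metric_pvalue,
    _null_basis,
    _pair_engine,
    _pair_rng,
)
from .metrics import METRICS, MetricParams, _score_rows
from .otu_io import prevalence_filter
from .simulate import (
    CommunityParams,
    default_planted_edges,
    generate_community,
    recovery_metrics,
    sample_reads,
)

__all__ = [
    "observe_community",
    "null_calibration",
    "pvalue_uniformity",
    "recovery_benchmark",
]


def observe_community(params: CommunityParams) -> IndexTable:
    """Community -> reads -> per-marker prevalence filter -> ensemble index."""
    truth = generate_community(params)
    tables = sample_reads(truth)
    return reduce(
        ensemble_index,
        [index_from_table(prevalence_filter(t)) for t in tables],
    )


def null_calibration(
    n_otus: int = 40,
    n_samples: int = 60,
    n_seeds: int = 20,
    n_perm: int = 100,
    n_boot: int = 100,
    q_threshold: float = 0.05,
    seed: int = 0,
) -> dict:
    """False-edge rate of the full pipeline on independent-OTU communities.

    Every OTU is statistically independent (no planted pairs, no shared
    environmental gradients), so every reported edge is a false positive;
    the rate is reported edges over consensus candidates, averaged over
    seeds.
    """
    rates = []
    edge_counts = []
    for i in range(n_seeds):
        s = int(seed + i) % (2**31 - 1)
        params = CommunityParams(
            n_otus=n_otus, n_samples=n_samples, n_env_gradients=0,
            planted_edges=(), seed=s,
        )
        idx = observe_community(params)
        cfg = InferenceConfig(n_perm=n_perm, n_boot=n_boot,
                              q_threshold=q_threshold, seed=s)
        net = infer_network(idx, cfg)
        candidates = max(1, net.provenance["n_consensus"])
        rates.append(len(net.edges) / candidates)
        edge_counts.append(len(net.edges))
    return {
        "n_seeds": n_seeds,
        "mean_false_edge_rate": float(np.mean(rates)),
        "per_seed_rates": rates,
        "mean_reported_edges": float(np.mean(edge_counts)),
    }


def pvalue_uniformity(
    n_otus: int = 40,
    n_samples: int = 60,
    n_pairs: int = 200,
    n_perm: int = 100,
    seed: int = 0,
) -> dict[str, float]:
    """Kolmogorov-Smirnov distance of per-metric null p-values from U(0,1).

    On an independent-OTU community the permutation p-values should be
    approximately uniform; large KS distances would signal a
    mis-calibrated null.
    """
    params = CommunityParams(
        n_otus=n_otus, n_samples=n_samples, n_env_gradients=0,
        planted_edges=(), seed=seed,
    )
    idx = observe_community(params)
    basis = _null_basis(idx)
    V = basis.V
    otus = idx.otu_ids
    pos = {o: i for i, o in enumerate(otus)}
    all_pairs = [(a, b) for i, a in enumerate(otus) for b in otus[i + 1 :]]
    # a seeded random pair sample spreads the shared-OTU dependence that
    # a contiguous block of pairs would concentrate on a few OTUs
    picker = np.random.default_rng(seed)
    take = min(n_pairs, len(all_pairs))
    pairs = [all_pairs[i] for i in picker.choice(len(all_pairs), take, replace=False)]
    mp = MetricParams()
    pvals: dict[str, list[float]] = {m: [] for m in METRICS}
    for a, b in pairs:
        rng = _pair_rng(seed, a, b)
        nulls, boots = _pair_engine(
            basis, pos[a], pos[b], METRICS, n_perm, 1, rng, mp
        )
        for m in METRICS:
            obs = float(_score_rows(m, V[pos[a]][None, :], V[pos[b]][None, :], mp)[0])
            p, _ = metric_pvalue(obs, nulls[m], boots[m])
            pvals[m].append(p)
    return {m: float(stats.kstest(v, "uniform").statistic) for m, v in pvals.items()}


def recovery_benchmark(
    n_otus: int = 110,
    n_samples: int = 60,
    n_copresence: int = 20,
    n_exclusion: int = 10,
    strength: float = 0.9,
    n_seeds: int = 3,
    n_perm: int = 100,
    n_boot: int = 100,
    seed: int = 0,
) -> dict:
    """Recovery of planted associations, pooled over seeds.

    Recall counts planted pairs whose endpoints survived the prevalence
    filter; sign accuracy is reported separately for planted co-presences
    and exclusions.
    """
    tot = {
        "copresence_eligible": 0, "copresence_recovered": 0, "copresence_sign_ok": 0,
        "exclusion_eligible": 0, "exclusion_recovered": 0, "exclusion_sign_ok": 0,
        "n_inferred": 0,
    }
    for i in range(n_seeds):
        s = int(seed + 1000 + i) % (2**31 - 1)
        planted = default_planted_edges(n_copresence, n_exclusion, strength, n_otus)
        params = CommunityParams(
            n_otus=n_otus, n_samples=n_samples, planted_edges=planted, seed=s
        )
        truth = generate_community(params)
        tables = sample_reads(truth)
        idx = reduce(
            ensemble_index,
            [index_from_table(prevalence_filter(t)) for t in tables],
        )
        net = infer_network(idx, InferenceConfig(n_perm=n_perm, n_boot=n_boot, seed=s))
        inferred = {tuple(sorted((e.otu_a, e.otu_b))): e.sign for e in net.edges}
        tot["n_inferred"] += len(inferred)
        nodes = set(net.nodes)
        for a, b, sign, _ in planted:
            if a not in nodes or b not in nodes:
                continue
            key = tuple(sorted((a, b)))
            tot[f"{sign}_eligible"] += 1
            if key in inferred:
                tot[f"{sign}_recovered"] += 1
                tot[f"{sign}_sign_ok"] += inferred[key] == sign
    out: dict = dict(tot)
    eligible = tot["copresence_eligible"]
    out["recall_copresence"] = (
        tot["copresence_recovered"] / eligible if eligible else None
    )
    out["sign_accuracy_copresence"] = (
        tot["copresence_sign_ok"] / tot["copresence_recovered"]
        if tot["copresence_recovered"] else None
    )
    excl = tot["exclusion_recovered"]
    out["recall_exclusion"] = (
        tot["exclusion_recovered"] / tot["exclusion_eligible"]
        if tot["exclusion_eligible"] else None
    )
    out["sign_accuracy_exclusion"] = tot["exclusion_sign_ok"] / excl if excl else None
    return out
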