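"""Enrichment statistics for response clusters and binding-site tags.

Cluster-level enrichment of a gene property (e.g. being a primary
receptor target) uses the one-tailed hypergeometric upper tail; the
global question of whether such genes distribute randomly across clusters
uses a Monte-Carlo multinomial goodness-of-fit test.  Tag-count shifts
between conditions are compared with the Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def hypergeom_enrichment(N: int, K: int, n: int, k: int) -> float:
    """One-tailed (upper) hypergeometric probability of observing >= k
    successes in a cluster of size n, given K successes among N genes.

    p = sum_{x=k..min(n,K)} C(K,x) C(N-K,n-x) / C(N,n), in log space.
    """
    N, K, n, k = (int(v) for v in (N, K, n, k))
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    # sf(k-1) = P(X >= k)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentResult:
    cluster: object
    n: int
    k: int
    K: int
    N: int
    expected: float
    p: float


def cluster_enrichment(
    assignments: pd.Series, successes: pd.Series
) -> pd.DataFrame:
    """Per-cluster hypergeometric enrichment of a boolean gene property.

    ``assignments`` maps gene -> cluster; ``successes`` maps gene -> bool.
    The expected proportion is the overall success fraction.
    """
    successes = successes.reindex(assignments.index).fillna(False).astype(bool)
    N = len(assignments)
    K = int(successes.sum())
    rows = []
    for cluster, genes in assignments.groupby(assignments):
        n = len(genes)
        k = int(successes.loc[genes.index].sum())
        rows.append(
            {
                "cluster": cluster,
                "size": n,
                "successes": k,
                "percent": 100.0 * k / n if n else np.nan,
                "expected_percent": 100.0 * K / N,
                "p": hypergeom_enrichment(N, K, n, k),
            }
        )
    return pd.DataFrame(rows)


def multinomial_cluster_test(
    observed,
    cluster_sizes,
    n_sim: int = 10_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo multinomial goodness-of-fit p-value.

    Tests whether ``observed`` successes distribute across clusters in
    proportion to cluster sizes.  The statistic is the multinomial
    log-likelihood of the counts under the size-proportional expectation;
    ``p = (1 + #{simulated loglik <= observed loglik}) / (1 + n_sim)``.
    """
    obs = np.asarray(observed, dtype=np.int64)
    sizes = np.asarray(cluster_sizes, dtype=float)
    probs = sizes / sizes.sum()
    K = int(obs.sum())
    obs_ll = stats.multinomial.logpmf(obs, K, probs)
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(K, probs, size=n_sim)
    sim_ll = stats.multinomial.logpmf(draws, K, probs)
    return float((1 + np.sum(sim_ll <= obs_ll)) / (1 + n_sim))


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney rank-sum U and two-sided p.

    Exact enumeration when n*m <= 400 and the pooled sample is tie-free;
    otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def percent_increase(a: float, b: float) -> float:
    """Percent change of a summary statistic relative to a baseline b > 0."""
    if b <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (a - b) / b
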