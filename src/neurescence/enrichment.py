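"""Hypergeometric machinery: tail probabilities, BH adjustment, pathway
over-representation and multi-set intersection significance.

All tail probabilities are computed in log space so that extremely small
values (down to 1e-400 and below on the log scale) remain meaningful; the
linear-scale value underflows to 0.0 below ~1e-308, so callers interested
in extreme tails should request the log.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom, hypergeom

from ._random import substream

logger = logging.getLogger(__name__)

__all__ = [
    "hypergeom_tail",
    "bh_adjust",
    "pathway_enrichment",
    "multiset_intersection_test",
]


def hypergeom_tail(k: int, K: int, n: int, N: int, log: bool = False) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the population size, K the number of successes in the population,
    n the number of draws, k the observed overlap. With ``log=True`` the
    natural log of the probability is returned (finite far below the
    smallest positive float).
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent parameters: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k <= max(0, K + n - N):
        return 0.0 if log else 1.0
    support = np.arange(k, min(K, n) + 1)
    logp = float(logsumexp(hypergeom.logpmf(support, N, K, n)))
    logp = min(logp, 0.0)
    return logp if log else float(np.exp(logp))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotone enforcement."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adj, 1.0)
    return out


def pathway_enrichment(query, collection, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of *query* genes in each set of
    *collection*, against *universe*.

    Query genes outside the universe are dropped with a warning; each set
    is intersected with the universe. Rows are sorted by adjusted p, then
    set name.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    query = list(dict.fromkeys(query))
    outside = [g for g in query if g not in uni]
    if outside:
        logger.warning("dropping %d query genes outside the universe", len(outside))
    query = [g for g in query if g in uni]
    if not query:
        raise ValueError("empty query after restricting to the universe")
    qset = set(query)
    N, n = len(uni), len(query)
    rows = []
    for name, genes in collection.sets.items():
        members = [g for g in genes if g in uni]
        overlap = [g for g in members if g in qset]
        K, k = len(members), len(overlap)
        p = hypergeom_tail(k, K, n, N)
        rows.append(
            {
                "set": name,
                "set_size": K,
                "overlap": k,
                "overlap_genes": ",".join(overlap),
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    df["adj_p"] = bh_adjust(np.clip(df["p"].to_numpy(), np.nextafter(0, 1), 1.0))
    df = df.sort_values(["adj_p", "set"], kind="stable").reset_index(drop=True)
    return df


def multiset_intersection_test(
    sets,
    universe_size: int,
    observed_intersection: int | None = None,
    method: str = "binomial",
    n_mc: int = 10000,
    seed: int = 0,
    log: bool = False,
) -> float:
    """Significance of the common intersection of several fixed-size sets.

    Under the null, each set is an independent uniform draw of its size
    from a universe of ``universe_size`` elements; an element then belongs
    to all sets with probability prod(n_i / N). The default ``binomial``
    method uses the Binomial(N, prod n_i/N) upper tail (an independence
    approximation, accurate for small n_i/N); ``montecarlo`` draws random
    subsets and reports an empirical tail with add-one smoothing.

    *sets* may be collections of elements (then ``observed_intersection``
    defaults to the size of their actual common intersection) or plain
    integer sizes (then it is required).
    """
    N = int(universe_size)
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    if all(isinstance(s, (int, np.integer)) for s in sets):
        sizes = [int(s) for s in sets]
        if observed_intersection is None:
            raise ValueError("observed_intersection required when sets are given as sizes")
    else:
        sets = [list(s) for s in sets]
        sizes = [len(s) for s in sets]
        if observed_intersection is None:
            inter = set(sets[0])
            for s in sets[1:]:
                inter &= set(s)
            observed_intersection = len(inter)
    obs = int(observed_intersection)
    if any(sz > N or sz < 0 for sz in sizes):
        raise ValueError("set sizes must lie in [0, universe size]")
    if obs > min(sizes):
        raise ValueError("observed intersection exceeds the smallest set")
    if method == "binomial":
        p_elem = float(np.prod([sz / N for sz in sizes]))
        if obs <= 0:
            return 0.0 if log else 1.0
        if log:
            return float(binom.logsf(obs - 1, N, p_elem))
        return float(binom.sf(obs - 1, N, p_elem))
    if method == "montecarlo":
        rng = substream(seed, "multiset_mc")
        hits = 0
        for _ in range(int(n_mc)):
            inter = None
            for sz in sizes:
                draw = set(rng.choice(N, size=sz, replace=False).tolist())
                inter = draw if inter is None else (inter & draw)
                if len(inter) < obs:
                    break
            if inter is not None and len(inter) >= obs:
                hits += 1
        p = (1 + hits) / (1 + int(n_mc))
        return float(np.log(p)) if log else float(p)
    raise ValueError(f"unknown method {method!r}")
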