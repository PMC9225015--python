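"""Hypergeometric over-representation analysis with Benjamini-Hochberg FDR.

Given a small query list (e.g. a gene's top co-dependent partners), each
gene set in a collection is tested for enrichment with the exact upper-tail
hypergeometric probability

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n)

where N is the universe size, K the set size within the universe, n the
query size within the universe and k the overlap. p-values are adjusted
across all tested sets with the BH step-up procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import lgamma

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .containers import GeneSetCollection, canonicalize_symbol

logger = logging.getLogger(__name__)


def _log_comb(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Hypergeom(N, K, n).

    Accumulated in log space term by term, stable for N up to ~1e5.
    """
    if not (0 <= n <= N and 0 <= K <= N and 0 <= k <= n):
        raise ValueError(f"invalid hypergeometric bounds: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    hi = min(K, n)
    lo = max(k, n - (N - K))  # need n - i <= N - K for a nonzero term
    if lo > hi:
        return 0.0
    log_denom = _log_comb(N, n)
    terms = [
        _log_comb(K, i) + _log_comb(N - K, n - i) - log_denom
        for i in range(lo, hi + 1)
    ]
    m = max(terms)
    total = m + np.log(np.sum(np.exp(np.asarray(terms) - m)))
    return float(min(1.0, np.exp(total)))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, original order preserved.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class EnrichmentResult:
    """ORA output: one row per tested set, ordered by q then p then set_id."""

    table: pd.DataFrame
    universe_size: int
    query_size: int
    dropped_genes: frozenset[str]

    def top_term(self, fdr: float = 0.05) -> tuple[str, str, float] | None:
        """(set_id, name, q) of the best term with q below ``fdr``, else None."""
        sig = self.table[self.table["q"] < fdr]
        if sig.empty:
            return None
        row = sig.iloc[0]
        return str(row["set_id"]), str(row["name"]), float(row["q"])


def ora(
    query,
    collection: GeneSetCollection,
    config: AnalysisConfig | None = None,
    universe: set[str] | None = None,
) -> EnrichmentResult:
    """Over-representation of each collection set in the query gene list.

    Query and every set are intersected with the universe before counting;
    sets empty within the universe are not tested. Query genes outside the
    universe are dropped with a warning.
    """
    config = config or AnalysisConfig()
    uni = frozenset(universe) if universe is not None else collection.universe
    uni = frozenset(canonicalize_symbol(g) for g in uni)
    q_raw = {canonicalize_symbol(g) for g in query}
    q_set = q_raw & uni
    dropped = frozenset(q_raw - uni)
    if dropped:
        logger.warning("query genes outside universe dropped: %s", sorted(dropped))
    if not q_set:
        raise ValueError(
            f"query is empty after restriction to the universe; dropped: {sorted(dropped)}"
        )
    N = len(uni)
    n = len(q_set)
    rows = []
    for set_id in sorted(collection.sets):
        name, members = collection.sets[set_id]
        members_u = members & uni
        K = len(members_u)
        if K < 1:
            continue
        k = len(q_set & members_u)
        rows.append(
            {
                "set_id": set_id,
                "name": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeometric_tail(k, K, n, N),
            }
        )
    table = pd.DataFrame(rows, columns=["set_id", "name", "k", "K", "n", "N", "p"])
    if len(table):
        table["q"] = bh_fdr(table["p"].to_numpy())
        table["significant"] = table["q"] < config.ora_fdr
        table = table.sort_values(
            ["q", "p", "set_id"], kind="stable"
        ).reset_index(drop=True)
    else:
        table["q"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return EnrichmentResult(
        table=table, universe_size=N, query_size=n, dropped_genes=dropped
    )
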