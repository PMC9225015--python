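"""Proteomics co-expression, interaction compilation and perturbation similarity.

Co-expression: pairwise-complete Pearson correlation of protein abundances
between a query gene and every other protein, restricted to partner pairs
detected in at least ``min_shared_lines`` cell lines (default 100).
Significance requires BH-adjusted p < ``coexpr_fdr`` AND |z| > ``coexpr_z``,
where z standardizes the query's vector of partner correlations
(z_i = (r_i - mean(r)) / sd(r), sample sd).

Interaction sets from multiple databases are compiled by edge union with
provenance tracking. Perturbation-signature similarity is consumed as a tau
table; hits with tau strictly above the threshold (default 90) are flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import pairwise_complete_pearson, pearson_pvalue
from .config import AnalysisConfig
from .containers import (
    AbundancePanel,
    InteractionSet,
    SimilarityTable,
    canonicalize_symbol,
)
from .enrichment import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class CoexpressionResult:
    """Per-partner co-expression statistics for one query gene.

    The FDR family is the query's eligible partners: partners failing the
    shared-detection rule are excluded before testing and never enter the
    family.
    """

    query: str
    table: pd.DataFrame  # columns: partner, r, n, p, q, z, significant
    n_excluded: int

    def significant_partners(self) -> set[str]:
        return set(self.table.loc[self.table["significant"], "partner"])


def coexpression_scan(
    ab: AbundancePanel, gene: str, config: AnalysisConfig | None = None
) -> CoexpressionResult:
    """Correlate one protein's abundance against every other protein."""
    config = config or AnalysisConfig()
    q = canonicalize_symbol(gene)
    if q not in ab.abundance.index:
        raise KeyError(f"gene {q!r} not in abundance panel")
    x = ab.abundance.loc[q].to_numpy()
    rows = []
    n_excluded = 0
    values = ab.abundance.to_numpy()
    for i, partner in enumerate(ab.genes):
        if partner == q:
            continue
        res = pairwise_complete_pearson(x, values[i], min_n=config.min_shared_lines)
        if res is None:
            n_excluded += 1
            continue
        r, n = res
        rows.append({"partner": partner, "r": r, "n": n, "p": pearson_pvalue(r, n)})
    if not rows:
        raise ValueError(
            f"no partner of {q} shares >= {config.min_shared_lines} detected lines"
        )
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    r_vec = df["r"].to_numpy()
    sd = float(np.std(r_vec, ddof=1)) if len(r_vec) > 1 else 0.0
    if sd == 0.0:
        raise ValueError(
            f"partner correlations of {q} have zero spread; z undefined "
            "(a larger panel is needed)"
        )
    df["z"] = (r_vec - r_vec.mean()) / sd
    df["significant"] = (df["q"] < config.coexpr_fdr) & (df["z"].abs() > config.coexpr_z)
    df = df.sort_values(["q", "p", "partner"], kind="stable").reset_index(drop=True)
    return CoexpressionResult(query=q, table=df, n_excluded=n_excluded)


def compile_interactions(sources: list[InteractionSet]) -> InteractionSet:
    """Union of interaction sets; provenance merges per edge. Idempotent."""
    if not sources:
        raise ValueError("at least one interaction source required")
    merged = InteractionSet()
    for src in sources:
        merged = merged.union(src)
    return merged


def interactors(iset: InteractionSet, gene: str) -> set[str]:
    """All interaction partners of a gene; empty set if the gene is absent."""
    return iset.neighbors(gene)


def similarity_flags(
    table: SimilarityTable, query: str, config: AnalysisConfig | None = None
) -> set[str]:
    """Hit genes with tau strictly above the threshold for one query.

    Duplicate (query, hit) rows are resolved to the maximum tau before
    thresholding; tau exactly at the threshold is not flagged.
    """
    config = config or AnalysisConfig()
    hits = table.hits_for(query)
    return set(hits.index[hits > config.tau_threshold])


def similarity_tested(table: SimilarityTable, query: str) -> set[str]:
    """Hit genes with any tau row for this query ("tested", flagged or not)."""
    return set(table.hits_for(query).index)


def rank_similarity(list_a, list_b) -> float:
    """Kendall-style concordance between two ranked gene lists.

    Over the m genes common to both lists, counts concordant minus
    discordant pairs divided by m(m-1)/2: 1 for identical order, -1 for
    reversed. Genes absent from either list are ignored. This is an
    auxiliary rank statistic, not a reimplementation of the consumed
    compendium-percentile tau scores.
    """
    a = [canonicalize_symbol(g) for g in list_a]
    b = [canonicalize_symbol(g) for g in list_b]
    pos_b = {g: i for i, g in enumerate(b)}
    common = [g for g in a if g in pos_b]
    m = len(common)
    if m < 2:
        raise ValueError(f"need >= 2 common genes, got {m}")
    ranks = [pos_b[g] for g in common]  # b-ranks in a-order
    concordant = discordant = 0
    for i in range(m):
        for j in range(i + 1, m):
            if ranks[i] < ranks[j]:
                concordant += 1
            else:
                discordant += 1
    return (concordant - discordant) / (m * (m - 1) / 2)
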