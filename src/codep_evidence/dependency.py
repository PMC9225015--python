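"""Essentiality summaries, lineage contrasts and co-dependency profiling.

A gene's dependent fraction is the share of cell lines whose dependency
score falls strictly below the threshold (default -0.5, the recommended
CERES cutoff). Lineage-specific sensitivity is scanned with Welch two-sided
t-tests (one lineage vs all other lines), BH-corrected across every
(gene, lineage) pair tested in the run. Co-dependency is the
pairwise-complete Pearson correlation of two genes' dependency vectors
across the panel; the top-k co-dependent partners feed the downstream
evidence integration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import pairwise_complete_pearson, pearson_pvalue
from .config import AnalysisConfig
from .containers import AbundancePanel, DependencyPanel, canonicalize_symbol
from .enrichment import bh_fdr

logger = logging.getLogger(__name__)

ESSENTIALITY_CATEGORIES = ("pan", "strong", "partial", "rare", "none")


def dependent_fraction(
    panel: DependencyPanel, gene: str, threshold: float = -0.5
) -> tuple[float, int, int]:
    """Fraction of tested (non-missing) lines with score strictly below threshold.

    Returns ``(fraction, n_dependent, n_tested)``.
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    scores = panel.gene_scores(gene)
    tested = scores.dropna()
    n_tested = int(len(tested))
    if n_tested == 0:
        raise ValueError(f"gene {gene!r} has no non-missing scores")
    n_dep = int((tested < threshold).sum())
    return n_dep / n_tested, n_dep, n_tested


def _categorize(fraction: float, n_dependent: int, n_tested: int, min_dependent_lines: int) -> str:
    # first matching rule wins; "partial" is >= 1% of tested lines
    if fraction >= 0.9:
        return "pan"
    if fraction >= 0.30:
        return "strong"
    if n_dependent >= math.ceil(0.01 * n_tested):
        return "partial"
    if n_dependent >= min_dependent_lines:
        return "rare"
    return "none"


def summarize_essentiality(
    panel: DependencyPanel, genes, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Per-gene dependent fraction and essentiality category.

    Categories (mutually exclusive, first match): pan (fraction >= 0.9),
    strong (>= 0.30), partial (n_dependent >= 1% of tested lines), rare
    (n_dependent >= min_dependent_lines), none.
    """
    config = config or AnalysisConfig()
    rows = []
    for gene in genes:
        g = canonicalize_symbol(gene)
        frac, n_dep, n_tested = dependent_fraction(
            panel, g, config.dependency_threshold
        )
        rows.append(
            {
                "gene": g,
                "fraction": frac,
                "n_dependent": n_dep,
                "n_tested": n_tested,
                "category": _categorize(frac, n_dep, n_tested, config.min_dependent_lines),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "fraction", "n_dependent", "n_tested", "category"]
    )


@dataclass
class LineageContrast:
    """One lineage-vs-rest Welch t-test for one gene.

    ``diff = mean_out - mean_in``: positive when the lineage is more
    sensitive (more negative scores) than the rest of the panel.
    """

    gene: str
    lineage: str
    n_in: int
    n_out: int
    mean_in: float
    mean_out: float
    diff: float
    t_stat: float
    p: float
    q: float = float("nan")


def lineage_contrast(
    panel: DependencyPanel,
    gene: str,
    lineage: str,
    config: AnalysisConfig | None = None,
) -> LineageContrast:
    """Welch two-sided t-test of one lineage's scores vs all other lines."""
    config = config or AnalysisConfig()
    gene = canonicalize_symbol(gene)
    scores = panel.gene_scores(gene)
    in_mask = panel.lineage == lineage
    x_in = scores[in_mask].dropna().to_numpy()
    x_out = scores[~in_mask].dropna().to_numpy()
    if len(x_in) < config.min_lineage_size:
        raise ValueError(
            f"lineage {lineage!r} has {len(x_in)} non-missing scores for {gene}, "
            f"fewer than min_lineage_size={config.min_lineage_size}"
        )
    if len(x_out) < 2:
        raise ValueError(f"out-group for {gene}/{lineage} too small ({len(x_out)})")
    t, p = stats.ttest_ind(x_in, x_out, equal_var=False)
    mean_in = float(x_in.mean())
    mean_out = float(x_out.mean())
    return LineageContrast(
        gene=gene,
        lineage=str(lineage),
        n_in=len(x_in),
        n_out=len(x_out),
        mean_in=mean_in,
        mean_out=mean_out,
        diff=mean_out - mean_in,
        t_stat=float(t),
        p=float(p),
    )


@dataclass
class LineageScanResult:
    table: pd.DataFrame
    skipped: pd.DataFrame = field(default_factory=pd.DataFrame)


_SCAN_COLUMNS = [
    "gene", "lineage", "n_in", "n_out", "mean_in", "mean_out",
    "diff", "t", "p", "q", "significant",
]


def scan_lineages(
    panel: DependencyPanel, genes, config: AnalysisConfig | None = None
) -> LineageScanResult:
    """All (gene, eligible lineage) contrasts with a single global BH family.

    A pair is flagged significant when raw p < lineage_p and BH q <
    lineage_fdr. Pairs skipped for size reasons are reported separately
    with reason codes, never silently dropped.
    """
    config = config or AnalysisConfig()
    rows: list[LineageContrast] = []
    skipped: list[dict] = []
    lineages = sorted(panel.lineage.unique())
    for gene in genes:
        g = canonicalize_symbol(gene)
        scores = panel.gene_scores(g)
        for lin in lineages:
            in_mask = panel.lineage == lin
            n_in = int(scores[in_mask].notna().sum())
            n_out = int(scores[~in_mask].notna().sum())
            if n_in < config.min_lineage_size:
                skipped.append(
                    {"gene": g, "lineage": lin, "reason": "lineage_below_min_size", "n_in": n_in}
                )
                continue
            if n_out < 2:
                skipped.append(
                    {"gene": g, "lineage": lin, "reason": "outgroup_too_small", "n_in": n_in}
                )
                continue
            rows.append(lineage_contrast(panel, g, lin, config))
    if not rows:
        raise ValueError("no eligible (gene, lineage) pairs to test")
    table = pd.DataFrame(
        [
            {
                "gene": c.gene, "lineage": c.lineage, "n_in": c.n_in, "n_out": c.n_out,
                "mean_in": c.mean_in, "mean_out": c.mean_out, "diff": c.diff,
                "t": c.t_stat, "p": c.p,
            }
            for c in rows
        ]
    )
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["significant"] = (table["p"] < config.lineage_p) & (table["q"] < config.lineage_fdr)
    table = table[_SCAN_COLUMNS]
    table = table.sort_values(["q", "p", "gene", "lineage"], kind="stable").reset_index(drop=True)
    skipped_df = pd.DataFrame(skipped, columns=["gene", "lineage", "reason", "n_in"])
    return LineageScanResult(table=table, skipped=skipped_df)


@dataclass
class CodependencyProfile:
    """Ranked co-dependency partners of one query gene."""

    query: str
    partners: pd.DataFrame  # columns: gene, r, n

    def top(self, k: int) -> pd.DataFrame:
        if k < 1:
            raise ValueError("k must be >= 1")
        return self.partners.head(k).reset_index(drop=True)


def codependency_profile(
    panel: DependencyPanel, gene: str, config: AnalysisConfig | None = None
) -> CodependencyProfile:
    """Pairwise-complete Pearson correlation of one gene vs every other gene.

    Partners with fewer than ``min_codep_overlap`` shared non-missing lines,
    or zero variance over the shared support, are omitted (logged). Ranking
    follows ``top_k_mode``: "absolute" sorts by descending |r| (negative
    co-dependents can rank at the top), "positive" by descending r; ties
    break lexicographically by symbol.
    """
    config = config or AnalysisConfig()
    q = canonicalize_symbol(gene)
    x = panel.gene_scores(q).to_numpy()
    finite = np.isfinite(x)
    if finite.sum() >= 2 and np.nanstd(x) == 0:
        raise ValueError(f"query gene {q} is constant; correlation undefined")
    rows = []
    n_skipped = 0
    values = panel.scores.to_numpy()
    for j, partner in enumerate(panel.genes):
        if partner == q:
            continue
        res = pairwise_complete_pearson(x, values[:, j], min_n=config.min_codep_overlap)
        if res is None:
            n_skipped += 1
            continue
        r, n = res
        rows.append({"gene": partner, "r": r, "n": n})
    if n_skipped:
        logger.debug("%s: %d partner(s) omitted (overlap/variance)", q, n_skipped)
    if not rows:
        raise ValueError(f"no partner of {q} meets min_codep_overlap={config.min_codep_overlap}")
    df = pd.DataFrame(rows)
    if config.top_k_mode == "absolute":
        df["_key"] = -df["r"].abs()
    else:
        df["_key"] = -df["r"]
    df = df.sort_values(["_key", "gene"], kind="stable").drop(columns="_key")
    return CodependencyProfile(query=q, partners=df.reset_index(drop=True))


def top_codependents(profile: CodependencyProfile, k: int) -> list[tuple[str, float, int]]:
    """First min(k, available) entries of the ranked profile."""
    top = profile.top(k)
    return [(row.gene, row.r, int(row.n)) for row in top.itertuples(index=False)]


def dependency_abundance_correlation(
    dep: DependencyPanel,
    ab: AbundancePanel,
    gene: str,
    config: AnalysisConfig | None = None,
) -> tuple[float, float, int] | None:
    """Pearson r between a gene's dependency scores and protein abundance.

    Computed over cell lines with both values present; two-sided t-based p
    on n-2 df. Returns None (a reason-coded skip at the cohort level) when
    overlap is insufficient or the gene is absent from either panel.
    """
    config = config or AnalysisConfig()
    g = canonicalize_symbol(gene)
    if g not in dep.scores.columns or g not in ab.abundance.index:
        return None
    shared = dep.scores.index.intersection(ab.abundance.columns)
    x = dep.scores.loc[shared, g].to_numpy()
    y = ab.abundance.loc[g, shared].to_numpy()
    res = pairwise_complete_pearson(x, y, min_n=config.min_codep_overlap)
    if res is None:
        return None
    r, n = res
    return r, pearson_pvalue(r, n), n


def cohort_dependency_abundance(
    dep: DependencyPanel, ab: AbundancePanel, genes, config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Per-gene dependency-abundance correlations plus cohort medians."""
    rows = []
    skips = []
    for gene in genes:
        g = canonicalize_symbol(gene)
        res = dependency_abundance_correlation(dep, ab, g, config)
        if res is None:
            skips.append({"gene": g, "reason": "insufficient_overlap_or_absent"})
            continue
        r, p, n = res
        rows.append({"gene": g, "r": r, "p": p, "n": n})
    df = pd.DataFrame(rows, columns=["gene", "r", "p", "n"])
    summary = {
        "median_r": float(df["r"].median()) if len(df) else float("nan"),
        "median_p": float(df["p"].median()) if len(df) else float("nan"),
        "n_genes": int(len(df)),
        "n_skipped": len(skips),
    }
    return df, summary
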