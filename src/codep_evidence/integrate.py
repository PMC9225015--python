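"""Evidence integration across the four analysis streams.

Each (query gene, partner gene) pair receives four boolean flags —
co-dependency (partner in the query's top-k), perturbation similarity
(tau strictly above threshold), proteomics co-expression (significant per
the co-expression scan) and database interaction (edge in the compiled
interaction set) — and an evidence count equal to their sum (0-4). Pairs
with the co-dependency flag whose partner carries a ubiquitin-like
transferase (E3) annotation form the DUB-E3 network.

The module is presented as a statsmodels-style pair of objects:
:class:`DubEvidenceModel` holds the data panels and configuration;
``fit()`` runs every stream and returns a :class:`DubEvidenceResults`
carrying the integrated tables, per-query details and a text ``summary()``.
``run_pipeline`` is the file-to-file wrapper over the same objects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .association import (
    CoexpressionResult,
    coexpression_scan,
    compile_interactions,
    interactors,
    similarity_flags,
    similarity_tested,
)
from .config import AnalysisConfig
from .containers import (
    AbundancePanel,
    DependencyPanel,
    GeneSetCollection,
    InteractionSet,
    SimilarityTable,
    canonicalize_symbol,
)
from .dependency import (
    codependency_profile,
    summarize_essentiality,
    top_codependents,
)
from .enrichment import EnrichmentResult, ora

logger = logging.getLogger(__name__)

EVIDENCE_COLUMNS = [
    "query", "partner", "codependency", "similarity", "coexpression",
    "interaction", "evidence_count", "codep_r", "tau_tested", "in_panel",
]


def evidence_table(
    queries,
    topk: dict[str, list[tuple[str, float, int]]],
    sim_flagged: dict[str, set[str]],
    sim_tested: dict[str, set[str]],
    coexpr_sig: dict[str, set[str]],
    interactions: InteractionSet | None,
    panel_genes,
    exhaustive: bool = False,
    all_genes=None,
) -> pd.DataFrame:
    """One row per (query, partner) pair flagged in at least one stream.

    With ``exhaustive=True`` every (query, gene) pair over ``all_genes`` is
    emitted, including evidence-count-0 rows. ``tau_tested`` distinguishes
    "tested, not similar" from "no tau row for this pair". Partners absent
    from the dependency panel are retained and annotated (``in_panel``).
    """
    panel_genes = set(panel_genes)
    rows = []
    for query in queries:
        q = canonicalize_symbol(query)
        topk_map = {g: r for g, r, _ in topk.get(q, [])}
        flagged_sim = sim_flagged.get(q, set())
        tested_sim = sim_tested.get(q, set())
        flagged_coex = coexpr_sig.get(q, set())
        neigh = interactors(interactions, q) if interactions is not None else set()
        if exhaustive:
            domain = set(all_genes if all_genes is not None else panel_genes)
            domain.discard(q)
        else:
            domain = (set(topk_map) | flagged_sim | flagged_coex | neigh) - {q}
        outside = domain - panel_genes
        if outside and not exhaustive:
            logger.warning(
                "%s: %d flagged partner(s) absent from the dependency panel", q, len(outside)
            )
        for partner in sorted(domain):
            codep = partner in topk_map
            sim = partner in flagged_sim
            coex = partner in flagged_coex
            ppi = partner in neigh
            count = int(codep) + int(sim) + int(coex) + int(ppi)
            rows.append(
                {
                    "query": q,
                    "partner": partner,
                    "codependency": codep,
                    "similarity": sim,
                    "coexpression": coex,
                    "interaction": ppi,
                    "evidence_count": count,
                    "codep_r": topk_map.get(partner, np.nan),
                    "tau_tested": partner in tested_sim,
                    "in_panel": partner in panel_genes,
                }
            )
    df = pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["query", "evidence_count", "partner"],
            ascending=[True, False, True],
            kind="stable",
        ).reset_index(drop=True)
    return df


def ligase_network(evidence: pd.DataFrame, transferase_set) -> pd.DataFrame:
    """DUB-E3 edges: co-dependency-flagged pairs whose partner is a transferase.

    Edges are anchored on the co-dependency flag; the other three flags
    annotate the edge (the colored edge classes of the network figure).
    """
    tset = {canonicalize_symbol(g) for g in transferase_set}
    if not tset:
        raise ValueError("transferase set is empty")
    if not len(evidence):
        return evidence.copy()
    keep = evidence["codependency"] & evidence["partner"].isin(tset)
    cols = [
        "query", "partner", "codep_r", "interaction", "coexpression",
        "similarity", "evidence_count",
    ]
    return evidence.loc[keep, cols].reset_index(drop=True)


@dataclass
class DubSummary:
    """Tabular equivalent of the per-gene summary rings.

    Fields mirror the per-gene report: dependent fraction and essentiality
    category, the top enriched GO term of the top co-dependents (None when
    nothing clears the FDR cutoff), and the top-k co-dependent partners with
    their r, interaction flag and similarity/co-expression flag.
    """

    gene: str
    fraction: float
    n_dependent: int
    n_tested: int
    category: str
    codep_analyzed: bool
    top_go: tuple[str, str, float] | None
    partners: pd.DataFrame  # columns: gene, r, interaction, similarity, coexpression

    def to_row(self) -> dict:
        return {
            "gene": self.gene,
            "fraction": self.fraction,
            "n_dependent": self.n_dependent,
            "n_tested": self.n_tested,
            "category": self.category,
            "codep_analyzed": self.codep_analyzed,
            "top_go_id": self.top_go[0] if self.top_go else "NONE",
            "top_go_name": self.top_go[1] if self.top_go else "NONE",
            "top_go_q": self.top_go[2] if self.top_go else np.nan,
            "top_codependents": ";".join(self.partners["gene"]),
            "top_codependents_r": ";".join(f"{r:.4f}" for r in self.partners["r"]),
            "top_codependents_ppi": ";".join(
                "Y" if f else "N" for f in self.partners["interaction"]
            ),
            "top_codependents_simcoex": ";".join(
                "Y" if (s or c) else "N"
                for s, c in zip(self.partners["similarity"], self.partners["coexpression"])
            ),
        }


def dub_summary(
    gene: str,
    essentiality: pd.DataFrame,
    topk: dict[str, list[tuple[str, float, int]]],
    ora_results: dict[str, EnrichmentResult],
    sim_flagged: dict[str, set[str]],
    coexpr_sig: dict[str, set[str]],
    interactions: InteractionSet | None,
    config: AnalysisConfig | None = None,
) -> DubSummary:
    """Assemble one gene's summary record from the stream outputs."""
    config = config or AnalysisConfig()
    g = canonicalize_symbol(gene)
    match = essentiality[essentiality["gene"] == g]
    if match.empty:
        raise KeyError(f"gene {g!r} missing from the dependency stream")
    row = match.iloc[0]
    analyzed = g in topk
    partners_rows = []
    if analyzed:
        neigh = interactors(interactions, g) if interactions is not None else set()
        for partner, r, _ in topk[g]:
            partners_rows.append(
                {
                    "gene": partner,
                    "r": r,
                    "interaction": partner in neigh,
                    "similarity": partner in sim_flagged.get(g, set()),
                    "coexpression": partner in coexpr_sig.get(g, set()),
                }
            )
    partners = pd.DataFrame(
        partners_rows, columns=["gene", "r", "interaction", "similarity", "coexpression"]
    )
    top_go = None
    if g in ora_results:
        top_go = ora_results[g].top_term(config.ora_fdr)
    return DubSummary(
        gene=g,
        fraction=float(row["fraction"]),
        n_dependent=int(row["n_dependent"]),
        n_tested=int(row["n_tested"]),
        category=str(row["category"]),
        codep_analyzed=analyzed,
        top_go=top_go,
        partners=partners,
    )


class DubEvidenceModel:
    """Evidence-integration model over up to five data surfaces.

    Parameters
    ----------
    dependency : DependencyPanel
        CRISPR dependency scores (required; the co-dependency anchor).
    gene_sets : GeneSetCollection, optional
        For over-representation of top co-dependents and the transferase set.
    abundance : AbundancePanel, optional
    interactions : InteractionSet or list of InteractionSet, optional
        Compiled on construction when a list is given.
    similarity : SimilarityTable, optional
    queries : list of gene symbols, optional (default: every panel gene)
    transferase_set_id : str, optional
        Gene-set id used to build the DUB-E3 network.
    """

    def __init__(
        self,
        dependency: DependencyPanel,
        gene_sets: GeneSetCollection | None = None,
        abundance: AbundancePanel | None = None,
        interactions=None,
        similarity: SimilarityTable | None = None,
        queries=None,
        transferase_set_id: str | None = None,
        config: AnalysisConfig | None = None,
    ) -> None:
        self.dependency = dependency
        self.gene_sets = gene_sets
        self.abundance = abundance
        if isinstance(interactions, (list, tuple)):
            interactions = compile_interactions(list(interactions))
        self.interactions = interactions
        self.similarity = similarity
        if queries is None:
            queries = dependency.genes
        self.queries = [canonicalize_symbol(g) for g in queries]
        missing = [g for g in self.queries if g not in dependency.scores.columns]
        if missing:
            raise ValueError(f"query genes absent from the dependency panel: {missing[:5]}")
        self.transferase_set_id = transferase_set_id
        self.config = config or AnalysisConfig()

    @classmethod
    def from_files(
        cls,
        dependency_path,
        sample_info_path=None,
        gmt_path=None,
        abundance_path=None,
        ppi_paths=(),
        tau_path=None,
        queries=None,
        transferase_set_id=None,
        config: AnalysisConfig | None = None,
        lineage_column: str = "lineage",
    ) -> "DubEvidenceModel":
        dep = cio.read_dependency_matrix(dependency_path, sample_info_path, lineage_column)
        gene_sets = cio.read_gmt(gmt_path) if gmt_path else None
        ab = cio.read_abundance_matrix(abundance_path) if abundance_path else None
        isets = [
            cio.read_edge_list(p, source_label=Path(p).stem) for p in ppi_paths
        ]
        sim = cio.read_similarity_table(tau_path) if tau_path else None
        return cls(
            dependency=dep,
            gene_sets=gene_sets,
            abundance=ab,
            interactions=isets or None,
            similarity=sim,
            queries=queries,
            transferase_set_id=transferase_set_id,
            config=config,
        )

    def fit(self, exhaustive: bool = False) -> "DubEvidenceResults":
        """Run all streams for every query and integrate the evidence."""
        cfg = self.config
        essentiality = summarize_essentiality(self.dependency, self.queries, cfg)
        n_dep = dict(zip(essentiality["gene"], essentiality["n_dependent"]))

        topk: dict[str, list[tuple[str, float, int]]] = {}
        ora_results: dict[str, EnrichmentResult] = {}
        coexpr: dict[str, CoexpressionResult] = {}
        skips: list[dict] = []
        for q in self.queries:
            # the co-dependency stream is restricted to genes with enough
            # dependent lines for the correlation to be meaningful
            if n_dep[q] < cfg.min_dependent_lines:
                skips.append({"gene": q, "stage": "codependency", "reason": "too_few_dependent_lines"})
            else:
                try:
                    profile = codependency_profile(self.dependency, q, cfg)
                except ValueError as exc:
                    skips.append({"gene": q, "stage": "codependency", "reason": str(exc)})
                else:
                    topk[q] = top_codependents(profile, cfg.top_k)
            if q in topk and self.gene_sets is not None:
                try:
                    ora_results[q] = ora(
                        [g for g, _, _ in topk[q]],
                        self.gene_sets,
                        cfg,
                        universe=set(self.dependency.genes),
                    )
                except ValueError as exc:
                    skips.append({"gene": q, "stage": "enrichment", "reason": str(exc)})
            if self.abundance is not None:
                try:
                    coexpr[q] = coexpression_scan(self.abundance, q, cfg)
                except (KeyError, ValueError) as exc:
                    skips.append({"gene": q, "stage": "coexpression", "reason": str(exc)})

        sim_flagged = {
            q: similarity_flags(self.similarity, q, cfg) for q in self.queries
        } if self.similarity is not None else {}
        sim_tested = {
            q: similarity_tested(self.similarity, q) for q in self.queries
        } if self.similarity is not None else {}
        coexpr_sig = {q: res.significant_partners() for q, res in coexpr.items()}

        evidence = evidence_table(
            self.queries,
            topk,
            sim_flagged,
            sim_tested,
            coexpr_sig,
            self.interactions,
            panel_genes=self.dependency.genes,
            exhaustive=exhaustive,
            all_genes=self.dependency.genes,
        )

        network = pd.DataFrame()
        if self.gene_sets is not None and self.transferase_set_id is not None:
            network = ligase_network(
                evidence, self.gene_sets.members(self.transferase_set_id)
            )

        summaries = [
            dub_summary(
                q, essentiality, topk, ora_results, sim_flagged, coexpr_sig,
                self.interactions, cfg,
            )
            for q in self.queries
        ]
        return DubEvidenceResults(
            model=self,
            config=cfg,
            essentiality=essentiality,
            topk=topk,
            ora_results=ora_results,
            coexpression=coexpr,
            sim_flagged=sim_flagged,
            evidence=evidence,
            network=network,
            summaries=summaries,
            skips=pd.DataFrame(skips, columns=["gene", "stage", "reason"]),
        )


@dataclass
class DubEvidenceResults:
    """Fitted evidence integration: tables, per-query details, summary()."""

    model: DubEvidenceModel
    config: AnalysisConfig
    essentiality: pd.DataFrame
    topk: dict[str, list[tuple[str, float, int]]]
    ora_results: dict[str, EnrichmentResult]
    coexpression: dict[str, CoexpressionResult]
    sim_flagged: dict[str, set[str]]
    evidence: pd.DataFrame
    network: pd.DataFrame
    summaries: list[DubSummary] = field(default_factory=list)
    skips: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame([s.to_row() for s in self.summaries])

    def summary(self) -> str:
        lines = [
            "Evidence integration summary",
            "============================",
            f"queries: {len(self.model.queries)}   "
            f"panel: {self.model.dependency.n_lines} lines x {self.model.dependency.n_genes} genes",
            f"config hash: {self.config.digest()}",
            "",
            "Essentiality categories:",
        ]
        counts = self.essentiality["category"].value_counts()
        for cat in ("pan", "strong", "partial", "rare", "none"):
            if cat in counts:
                lines.append(f"  {cat:8s} {int(counts[cat])}")
        ev = self.evidence
        lines.append("")
        lines.append(f"Evidence pairs: {len(ev)}")
        if len(ev):
            vc = ev["evidence_count"].value_counts().sort_index()
            for count, n in vc.items():
                lines.append(f"  count {count}: {int(n)} pair(s)")
        lines.append(f"DUB-E3 network edges: {len(self.network)}")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write evidence, summary and network TSVs plus a run manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "evidence": outdir / "evidence.tsv",
            "summary": outdir / "summary.tsv",
            "network": outdir / "network.tsv",
            "skips": outdir / "skips.tsv",
            "manifest": outdir / "manifest.json",
        }
        cio.write_tsv(self.evidence, paths["evidence"])
        cio.write_tsv(self.summary_table, paths["summary"])
        net = self.network if len(self.network) else pd.DataFrame(
            columns=["query", "partner", "codep_r", "interaction", "coexpression",
                     "similarity", "evidence_count"]
        )
        cio.write_tsv(net, paths["network"])
        cio.write_tsv(self.skips, paths["skips"])
        manifest = {
            "config": self.config.to_dict(),
            "config_hash": self.config.digest(),
            "n_queries": len(self.model.queries),
            "n_lines": self.model.dependency.n_lines,
            "n_genes": self.model.dependency.n_genes,
            "n_evidence_pairs": int(len(self.evidence)),
            "n_network_edges": int(len(self.network)),
        }
        with open(paths["manifest"], "w", newline="\n") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return paths


def run_pipeline(
    config: AnalysisConfig,
    paths: dict,
    outdir: str | Path,
    queries=None,
    transferase_set_id: str | None = None,
) -> dict[str, Path]:
    """File-to-file pipeline: read inputs, fit the model, write outputs.

    ``paths`` keys: dependency, sample_info, gmt, abundance, ppi (list),
    tau — all but dependency optional. Deterministic given inputs + config;
    the thresholds used are echoed into the manifest. Any stage error aborts
    with the stage name.
    """
    try:
        model = DubEvidenceModel.from_files(
            dependency_path=paths["dependency"],
            sample_info_path=paths.get("sample_info"),
            gmt_path=paths.get("gmt"),
            abundance_path=paths.get("abundance"),
            ppi_paths=paths.get("ppi", ()),
            tau_path=paths.get("tau"),
            queries=queries,
            transferase_set_id=transferase_set_id,
            config=config,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc
    try:
        results = model.fit()
    except Exception as exc:
        raise RuntimeError(f"stage 'fit' failed: {exc}") from exc
    try:
        out = results.save(outdir)
    except Exception as exc:
        raise RuntimeError(f"stage 'save' failed: {exc}") from exc
    logger.info("pipeline complete: %s", {k: str(v) for k, v in out.items()})
    return out
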