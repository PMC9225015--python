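"""Synthetic multi-omics panels with planted ground truth.

The generator emulates the statistical structure the analysis assumes:
genes in the same planted complex share a latent per-cell-line factor, so
their dependency scores are correlated across the panel (co-dependency) and
their protein abundances are correlated across lines (co-expression);
designated genes get a lineage-specific essentiality shift; interaction
edges are drawn densely within complexes and sparsely elsewhere; the tau
table gives same-complex pairs high similarity and background pairs
mean-zero noise.

Dependency score model for gene g in cell line c:

    score(g, c) = base_mean + lambda_g * f_{m(g), c} + shift * 1[planted] + eps

with f a per-complex per-line standard-normal factor, lambda_g = factor_sd
for complex members (0 otherwise) and eps ~ Normal(0, noise_sd). Abundance
uses an analogous module-factor model with missing-completely-at-random
masking. The first member of each complex is the designated query
(DUB-analogue) and the second the designated E3-role gene; the gene-set
collection contains one set per complex plus a transferase set holding the
E3-role genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    AbundancePanel,
    DependencyPanel,
    GeneSetCollection,
    InteractionSet,
    SimilarityTable,
)

TRANSFERASE_SET_ID = "UBL_TRANSFERASE_ACTIVITY"


@dataclass
class SimConfig:
    n_genes: int = 200
    n_lines: int = 300
    n_lineages: int = 8
    complexes: list[int] = field(default_factory=lambda: [5, 5, 4, 4, 3])
    factor_sd: float = 0.6
    noise_sd: float = 0.3
    base_mean: float = -0.2
    # (gene index, lineage index, dependency-score shift)
    lineage_effects: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(0, 0, -0.5)]
    )
    abundance_missing_rate: float = 0.3
    ppi_within_prob: float = 0.8
    ppi_background_prob: float = 0.002
    tau_within: float = 95.0
    tau_background_sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.complexes) > self.n_genes:
            raise ValueError(
                f"sum of complex sizes ({sum(self.complexes)}) exceeds n_genes ({self.n_genes})"
            )
        for name in ("abundance_missing_rate", "ppi_within_prob", "ppi_background_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd <= 0 or self.tau_background_sd <= 0:
            raise ValueError("noise_sd and tau_background_sd must be positive")
        if self.factor_sd < 0:
            raise ValueError("factor_sd must be non-negative")
        if self.n_lineages < 1 or self.n_lines < self.n_lineages:
            raise ValueError("need n_lines >= n_lineages >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation draw, for recovery testing."""

    complex_membership: dict[str, int | None]
    lineage_effects: list[tuple[str, str, float]]
    true_edges: InteractionSet
    coexpr_modules: dict[str, int | None]
    query_genes: list[str]
    e3_genes: list[str]

    def genes(self) -> set[str]:
        return set(self.complex_membership)

    def planted_query_pairs(self) -> set[tuple[str, str]]:
        """(query, partner) pairs where both share a planted complex."""
        pairs = set()
        for q in self.query_genes:
            cid = self.complex_membership[q]
            if cid is None:
                continue
            for g, c in self.complex_membership.items():
                if g != q and c == cid:
                    pairs.add((q, g))
        return pairs

    def to_json(self, path: str | Path) -> None:
        payload = {
            "complex_membership": self.complex_membership,
            "lineage_effects": [list(t) for t in self.lineage_effects],
            "true_edges": [
                [a, b, sorted(self.true_edges.provenance(a, b))]
                for a, b in self.true_edges.edges
            ],
            "coexpr_modules": self.coexpr_modules,
            "query_genes": self.query_genes,
            "e3_genes": self.e3_genes,
        }
        with open(path, "w", newline="\n") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        edges = InteractionSet()
        for a, b, sources in payload["true_edges"]:
            edges.add(a, b, sources)
        return cls(
            complex_membership=payload["complex_membership"],
            lineage_effects=[tuple(t) for t in payload["lineage_effects"]],
            true_edges=edges,
            coexpr_modules=payload["coexpr_modules"],
            query_genes=payload["query_genes"],
            e3_genes=payload["e3_genes"],
        )


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _line_ids(n: int) -> list[str]:
    return [f"ACH-{100000 + i:06d}" for i in range(n)]


def simulate_panel(
    config: SimConfig,
) -> tuple[
    DependencyPanel,
    AbundancePanel,
    InteractionSet,
    SimilarityTable,
    GeneSetCollection,
    SyntheticTruth,
]:
    """Draw one synthetic bundle; deterministic given the config seed."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    lines = _line_ids(config.n_lines)
    lineage_labels = [f"LIN{j:02d}" for j in range(config.n_lineages)]

    # balanced random lineage assignment: shuffled round-robin
    assignment = np.array(
        [j % config.n_lineages for j in range(config.n_lines)], dtype=int
    )
    rng.shuffle(assignment)
    lineage = pd.Series(
        [lineage_labels[a] for a in assignment], index=lines, dtype=object
    )

    membership: dict[str, int | None] = {g: None for g in genes}
    idx = 0
    for cid, size in enumerate(config.complexes):
        for _ in range(size):
            membership[genes[idx]] = cid
            idx += 1
    member_complex = np.array(
        [-1 if membership[g] is None else membership[g] for g in genes], dtype=int
    )

    # dependency scores: complex latent factor + planted lineage shift + noise
    n_complexes = len(config.complexes)
    factors = rng.standard_normal((n_complexes, config.n_lines))
    scores = config.base_mean + rng.normal(
        0.0, config.noise_sd, size=(config.n_lines, config.n_genes)
    )
    for j, cid in enumerate(member_complex):
        if cid >= 0:
            scores[:, j] += config.factor_sd * factors[cid]
    planted_effects: list[tuple[str, str, float]] = []
    for gene_idx, lin_idx, shift in config.lineage_effects:
        mask = assignment == lin_idx
        scores[mask, gene_idx] += shift
        planted_effects.append((genes[gene_idx], lineage_labels[lin_idx], float(shift)))
    dep = DependencyPanel(
        scores=pd.DataFrame(scores, index=lines, columns=genes), lineage=lineage
    )

    # abundance: same module structure, gene-level offsets, MCAR missingness
    ab_factors = rng.standard_normal((n_complexes, config.n_lines))
    gene_means = rng.normal(0.0, 1.0, size=config.n_genes)
    abundance = gene_means[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, config.n_lines)
    )
    for j, cid in enumerate(member_complex):
        if cid >= 0:
            abundance[j] += config.factor_sd * ab_factors[cid]
    missing = rng.random((config.n_genes, config.n_lines)) < config.abundance_missing_rate
    abundance[missing] = np.nan
    ab = AbundancePanel(
        abundance=pd.DataFrame(abundance, index=genes, columns=lines)
    )

    # interaction edges: dense within complexes, sparse background;
    # each edge is attributed to one or both of two synthetic sources
    edges = InteractionSet()
    for i in range(config.n_genes):
        for j in range(i + 1, config.n_genes):
            same = member_complex[i] >= 0 and member_complex[i] == member_complex[j]
            prob = config.ppi_within_prob if same else config.ppi_background_prob
            if rng.random() < prob:
                code = rng.integers(0, 3)
                sources = ("ppi_a",) if code == 0 else ("ppi_b",) if code == 1 else ("ppi_a", "ppi_b")
                edges.add(genes[i], genes[j], sources)

    query_genes, e3_genes = [], []
    idx = 0
    for size in config.complexes:
        query_genes.append(genes[idx])
        if size >= 2:
            e3_genes.append(genes[idx + 1])
        idx += size

    # tau table: one row per (query, other gene)
    tau_rows = []
    for q in query_genes:
        qc = membership[q]
        for h in genes:
            if h == q:
                continue
            if membership[h] is not None and membership[h] == qc:
                tau = config.tau_within + rng.normal(0.0, 2.0)
            else:
                tau = rng.normal(0.0, config.tau_background_sd)
            tau_rows.append(
                {"query": q, "hit": h, "tau": float(np.clip(tau, -100.0, 100.0)),
                 "pert_type": "knockdown"}
            )
    sim_table = SimilarityTable(table=pd.DataFrame(tau_rows))

    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for cid, size in enumerate(config.complexes):
        members = frozenset(g for g, c in membership.items() if c == cid)
        sets[f"COMPLEX{cid:02d}"] = (f"Planted complex {cid}", members)
    n_extra = min(10, config.n_genes - sum(config.complexes))
    background = [g for g in genes if membership[g] is None]
    extra = list(rng.choice(background, size=n_extra, replace=False)) if n_extra else []
    sets[TRANSFERASE_SET_ID] = (
        "Ubiquitin-like protein transferase activity (designated E3-role genes)",
        frozenset(e3_genes) | frozenset(extra),
    )
    collection = GeneSetCollection(sets=sets, universe=frozenset(genes))

    truth = SyntheticTruth(
        complex_membership=membership,
        lineage_effects=planted_effects,
        true_edges=edges,
        coexpr_modules=dict(membership),
        query_genes=query_genes,
        e3_genes=e3_genes,
    )
    return dep, ab, edges, sim_table, collection, truth


def write_bundle(outdir: str | Path, config: SimConfig) -> dict[str, Path]:
    """Simulate and write all input files in the pipeline's on-disk formats."""
    from . import io as cio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dep, ab, edges, tau, collection, truth = simulate_panel(config)
    paths = {
        "dependency": outdir / "dependency.csv",
        "sample_info": outdir / "sample_info.csv",
        "abundance": outdir / "abundance.csv",
        "gmt": outdir / "gene_sets.gmt",
        "ppi_a": outdir / "ppi_a.tsv",
        "ppi_b": outdir / "ppi_b.tsv",
        "tau": outdir / "tau.tsv",
        "truth": outdir / "truth.json",
    }
    cio.write_dependency_matrix(dep, paths["dependency"], paths["sample_info"])
    cio.write_abundance_matrix(ab, paths["abundance"])
    cio.write_gmt(collection, paths["gmt"])
    for label, key in (("ppi_a", "ppi_a"), ("ppi_b", "ppi_b")):
        sub = InteractionSet()
        for a, b in edges.edges:
            if label in edges.provenance(a, b):
                sub.add(a, b, label)
        cio.write_edge_list(sub, paths[key])
    cio.write_similarity_table(tau, paths["tau"])
    truth.to_json(paths["truth"])
    return paths


def truth_recovery_report(truth: SyntheticTruth, evidence: pd.DataFrame) -> dict:
    """Precision/recall of planted same-complex pairs among evidence >= 2.

    ``evidence`` is an integrated evidence table (columns query, partner,
    evidence_count). Pairs absent from the table count as evidence 0. The
    background domain is every (query, non-planted partner) pair over the
    truth's gene universe.
    """
    genes = truth.genes()
    ev_genes = set(evidence["query"]) | set(evidence["partner"])
    unknown = ev_genes - genes
    if unknown:
        raise ValueError(f"evidence table contains genes outside the truth universe: {sorted(unknown)[:5]}")
    planted = truth.planted_query_pairs()
    counts = {
        (r.query, r.partner): int(r.evidence_count)
        for r in evidence.itertuples(index=False)
    }
    predicted = {pair for pair, c in counts.items() if c >= 2}
    tp = len(predicted & planted)
    precision = tp / len(predicted) if predicted else float("nan")
    recall = tp / len(planted) if planted else float("nan")
    planted_counts = [counts.get(pair, 0) for pair in sorted(planted)]
    background_counts = [
        counts.get((q, g), 0)
        for q in truth.query_genes
        for g in sorted(genes)
        if g != q and (q, g) not in planted
    ]
    return {
        "precision": precision,
        "recall": recall,
        "n_planted": len(planted),
        "n_predicted": len(predicted),
        "mean_evidence_planted": float(np.mean(planted_counts)) if planted_counts else float("nan"),
        "mean_evidence_background": float(np.mean(background_counts)) if background_counts else float("nan"),
    }
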