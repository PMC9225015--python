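"""In-memory containers for the five data surfaces the pipeline touches.

All containers join on HGNC-style gene symbols canonicalized by
:func:`canonicalize_symbol` (uppercase, surrounding whitespace stripped).
Missing values are represented by NaN throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

UNKNOWN_LINEAGE = "UNKNOWN"


def canonicalize_symbol(symbol: str) -> str:
    """Canonical gene symbol: strip surrounding whitespace, uppercase.

    Idempotent: ``canonicalize_symbol(canonicalize_symbol(s)) == canonicalize_symbol(s)``.
    """
    return str(symbol).strip().upper()


def _check_unique(labels: Iterable[str], what: str) -> None:
    counts = pd.Series(list(labels)).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise ValueError(
            f"duplicate {what} after canonicalization: {sorted(dups.index.tolist())}"
        )


@dataclass
class DependencyPanel:
    """Cell-line x gene matrix of dependency scores with lineage labels.

    Scores are CERES-like fitness effects: more negative means the line is
    more dependent on the gene. ``scores`` is indexed by cell-line id (rows)
    and gene symbol (columns); ``lineage`` maps every cell-line id to a free
    text lineage label (``"UNKNOWN"`` when unannotated).
    """

    scores: pd.DataFrame
    lineage: pd.Series
    entrez: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = self.scores.copy()
        self.scores.columns = [canonicalize_symbol(g) for g in self.scores.columns]
        _check_unique(self.scores.columns, "gene symbols")
        _check_unique(self.scores.index, "cell-line ids")
        lineage = pd.Series(self.lineage, dtype=object).map(
            lambda s: str(s).strip() if pd.notna(s) else UNKNOWN_LINEAGE
        )
        # every panel line carries a label, defaulting to UNKNOWN
        self.lineage = lineage.reindex(self.scores.index).fillna(UNKNOWN_LINEAGE)
        self.lineage.name = "lineage"

    @property
    def cell_lines(self) -> list[str]:
        return list(self.scores.index)

    @property
    def genes(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n_lines(self) -> int:
        return self.scores.shape[0]

    @property
    def n_genes(self) -> int:
        return self.scores.shape[1]

    def gene_scores(self, gene: str) -> pd.Series:
        gene = canonicalize_symbol(gene)
        if gene not in self.scores.columns:
            raise KeyError(f"gene {gene!r} not in dependency panel")
        return self.scores[gene]

    def lineage_sizes(self) -> pd.Series:
        return self.lineage.value_counts()

    def summary(self) -> dict:
        total = self.scores.size
        missing = int(self.scores.isna().sum().sum())
        return {
            "n_lines": self.n_lines,
            "n_genes": self.n_genes,
            "missing_fraction": missing / total if total else 0.0,
        }


@dataclass
class AbundancePanel:
    """Protein x cell-line matrix of normalized abundances; NaN = not detected."""

    abundance: pd.DataFrame

    def __post_init__(self) -> None:
        self.abundance = self.abundance.copy()
        self.abundance.index = [canonicalize_symbol(g) for g in self.abundance.index]
        _check_unique(self.abundance.index, "gene symbols")
        _check_unique(self.abundance.columns, "cell-line ids")

    @property
    def genes(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def detected(self) -> pd.DataFrame:
        """Boolean detection mask (non-missing cells)."""
        return self.abundance.notna()

    def shared_detection_count(self, gene_a: str, gene_b: str) -> int:
        """Number of cell lines in which both proteins were detected."""
        a = self.abundance.loc[canonicalize_symbol(gene_a)]
        b = self.abundance.loc[canonicalize_symbol(gene_b)]
        return int((a.notna() & b.notna()).sum())


@dataclass
class GeneSetCollection:
    """Named gene sets plus the universe of testable symbols (GMT-backed).

    ``sets`` maps set id to ``(display name, frozenset of member symbols)``.
    The universe defaults to the union of all members.
    """

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, frozenset[str]]] = {}
        for set_id, (name, members) in self.sets.items():
            clean[set_id] = (
                name,
                frozenset(canonicalize_symbol(m) for m in members),
            )
        self.sets = clean
        if self.universe is None:
            u: set[str] = set()
            for _, members in self.sets.values():
                u |= members
            self.universe = frozenset(u)
        else:
            self.universe = frozenset(canonicalize_symbol(m) for m in self.universe)

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]

    def name(self, set_id: str) -> str:
        return self.sets[set_id][0]


def canonical_edge(gene_a: str, gene_b: str) -> tuple[str, str]:
    a, b = canonicalize_symbol(gene_a), canonicalize_symbol(gene_b)
    return (a, b) if a < b else (b, a)


class InteractionSet:
    """Undirected interaction edges with per-edge source provenance.

    Edges are stored as lexicographically ordered symbol pairs; self-edges
    are rejected. Provenance is the non-empty set of source labels that
    reported the edge.
    """

    def __init__(
        self, edges: Mapping[tuple[str, str], Iterable[str]] | None = None
    ) -> None:
        self._edges: dict[tuple[str, str], set[str]] = {}
        if edges:
            for (a, b), sources in edges.items():
                self.add(a, b, sources)

    def add(self, gene_a: str, gene_b: str, sources: Iterable[str] | str) -> None:
        a, b = canonical_edge(gene_a, gene_b)
        if a == b:
            raise ValueError(f"self-edge not allowed: {a}")
        if isinstance(sources, str):
            sources = [sources]
        labels = {str(s) for s in sources}
        if not labels:
            raise ValueError(f"edge ({a}, {b}) has empty provenance")
        self._edges.setdefault((a, b), set()).update(labels)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self._edges)

    def provenance(self, gene_a: str, gene_b: str) -> frozenset[str]:
        return frozenset(self._edges[canonical_edge(gene_a, gene_b)])

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_edge(*pair) in self._edges

    def __len__(self) -> int:
        return len(self._edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionSet):
            return NotImplemented
        return self._edges == other._edges

    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self._edges:
            out.add(a)
            out.add(b)
        return out

    def neighbors(self, gene: str) -> set[str]:
        g = canonicalize_symbol(gene)
        out: set[str] = set()
        for a, b in self._edges:
            if a == g:
                out.add(b)
            elif b == g:
                out.add(a)
        return out

    def union(self, other: "InteractionSet") -> "InteractionSet":
        merged = InteractionSet()
        for (a, b), sources in self._edges.items():
            merged.add(a, b, sources)
        for (a, b), sources in other._edges.items():
            merged.add(a, b, sources)
        return merged

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, "sources": ";".join(sorted(self._edges[(a, b)]))}
            for a, b in self.edges
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "sources"])


@dataclass
class SimilarityTable:
    """Perturbation-similarity rows (query, hit, tau in [-100, 100]).

    tau is a percentile-style similarity between a query expression
    signature and a reference perturbation signature. Duplicate
    (query, hit) rows are resolved by keeping the maximum tau.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        required = {"query", "hit", "tau"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"similarity table missing columns: {sorted(missing)}")
        df["query"] = df["query"].map(canonicalize_symbol)
        df["hit"] = df["hit"].map(canonicalize_symbol)
        df["tau"] = df["tau"].astype(float)
        bad = df[(df["tau"] < -100) | (df["tau"] > 100) | ~np.isfinite(df["tau"])]
        if len(bad):
            raise ValueError(
                f"tau out of [-100, 100] for {len(bad)} rows, "
                f"first: {bad.iloc[0]['query']}-{bad.iloc[0]['hit']}"
            )
        self.table = df.reset_index(drop=True)

    def hits_for(self, query: str) -> pd.Series:
        """Max tau per hit gene for one query (duplicates collapsed)."""
        q = canonicalize_symbol(query)
        sub = self.table[self.table["query"] == q]
        if sub.empty:
            return pd.Series(dtype=float)
        return sub.groupby("hit")["tau"].max().sort_index()
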