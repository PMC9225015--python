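"""Readers and writers for the tabular formats the pipeline consumes.

Formats: dependency matrix CSV in the DepMap gene-effect dialect (header
cells ``SYMBOL (ENTREZ)``, ACH-style row ids) with a sample-info CSV for
lineage labels; protein abundance CSV (genes x lines); GMT gene-set files;
TSV interaction edge lists; TSV tau similarity tables. All writers emit
UTF-8 with LF line endings; missing values are written as empty cells.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pandas as pd

from .containers import (
    UNKNOWN_LINEAGE,
    AbundancePanel,
    DependencyPanel,
    GeneSetCollection,
    InteractionSet,
    SimilarityTable,
    canonicalize_symbol,
)

logger = logging.getLogger(__name__)

_ENTREZ_SUFFIX = re.compile(r"\s*\((\d+)\)\s*$")


def _split_symbol(header_cell: str) -> tuple[str, str | None]:
    """Split ``"A1CF (29974)"`` into ``("A1CF", "29974")``."""
    m = _ENTREZ_SUFFIX.search(header_cell)
    if m:
        return canonicalize_symbol(header_cell[: m.start()]), m.group(1)
    return canonicalize_symbol(header_cell), None


def read_dependency_matrix(
    matrix_path: str | Path,
    sample_info_path: str | Path | None = None,
    lineage_column: str = "lineage",
) -> DependencyPanel:
    """Read a DepMap-dialect gene-effect CSV plus a sample-info table.

    Gene symbols are extracted by stripping the parenthesized Entrez suffix;
    cell lines absent from the sample info get lineage ``"UNKNOWN"`` with a
    logged warning.
    """
    raw = pd.read_csv(matrix_path, index_col=0)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"empty dependency matrix: {matrix_path}")
    symbols, entrez = [], {}
    for cell in raw.columns:
        sym, ent = _split_symbol(cell)
        symbols.append(sym)
        if ent is not None:
            entrez[sym] = ent
    raw.columns = symbols
    raw.index = [str(i).strip() for i in raw.index]
    raw = raw.astype(float)

    lineage = pd.Series(UNKNOWN_LINEAGE, index=raw.index, dtype=object)
    if sample_info_path is not None:
        info = pd.read_csv(sample_info_path, index_col=0)
        if lineage_column not in info.columns:
            raise ValueError(
                f"sample info lacks column {lineage_column!r}; "
                f"found {list(info.columns)}"
            )
        info.index = [str(i).strip() for i in info.index]
        mapped = info[lineage_column].reindex(raw.index)
        n_missing = int(mapped.isna().sum())
        if n_missing:
            logger.warning(
                "%d cell line(s) absent from sample info; lineage set to %s",
                n_missing,
                UNKNOWN_LINEAGE,
            )
        lineage = mapped.fillna(UNKNOWN_LINEAGE).map(lambda s: str(s).strip())

    panel = DependencyPanel(scores=raw, lineage=lineage, entrez=entrez)
    logger.info("dependency panel: %s", panel.summary())
    return panel


def write_dependency_matrix(
    panel: DependencyPanel,
    matrix_path: str | Path,
    sample_info_path: str | Path | None = None,
    lineage_column: str = "lineage",
) -> None:
    out = panel.scores.copy()
    out.columns = [
        f"{g} ({panel.entrez[g]})" if g in panel.entrez else g for g in out.columns
    ]
    out.to_csv(matrix_path, lineterminator="\n")
    if sample_info_path is not None:
        info = pd.DataFrame({lineage_column: panel.lineage}).rename_axis("cell_line_id")
        info.to_csv(sample_info_path, lineterminator="\n")


def read_abundance_matrix(path: str | Path) -> AbundancePanel:
    """Read a protein-abundance CSV, genes as rows, cell lines as columns."""
    raw = pd.read_csv(path, index_col=0)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"empty abundance matrix: {path}")
    raw.columns = [str(c).strip() for c in raw.columns]
    return AbundancePanel(abundance=raw.astype(float))


def write_abundance_matrix(panel: AbundancePanel, path: str | Path) -> None:
    panel.abundance.rename_axis("gene_symbol").to_csv(path, lineterminator="\n")


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file: ``set_id TAB description TAB member...`` per line."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            set_id, name = fields[0], fields[1]
            members = frozenset(
                canonicalize_symbol(m) for m in fields[2:] if m.strip()
            )
            sets[set_id] = (name, members)
    return GeneSetCollection(sets=sets, universe=universe)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for set_id in sorted(collection.sets):
            name, members = collection.sets[set_id]
            fh.write("\t".join([set_id, name, *sorted(members)]) + "\n")


def read_edge_list(path: str | Path, source_label: str = "unknown") -> InteractionSet:
    """Read a TSV edge list with columns gene_a, gene_b (+ optional source).

    Edges are canonicalized to sorted pairs; self-edges are dropped with a
    logged count; duplicate rows merge their provenance.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_a", "gene_b"}
    if not required <= set(df.columns):
        raise ValueError(
            f"edge list {path} missing columns {sorted(required - set(df.columns))}; "
            f"found {list(df.columns)}"
        )
    iset = InteractionSet()
    n_self = 0
    # "sources" (;-joined) is the writer's own dialect; "source" a single label
    source_col = "sources" if "sources" in df.columns else (
        "source" if "source" in df.columns else None
    )
    for row in df.itertuples(index=False):
        a = canonicalize_symbol(row.gene_a)
        b = canonicalize_symbol(row.gene_b)
        if a == b:
            n_self += 1
            continue
        labels = [source_label]
        if source_col is not None:
            raw = getattr(row, source_col)
            if pd.notna(raw) and str(raw).strip():
                labels = [s for s in str(raw).split(";") if s]
        iset.add(a, b, labels)
    if n_self:
        logger.warning("%s: dropped %d self-edge(s)", path, n_self)
    return iset


def write_edge_list(iset: InteractionSet, path: str | Path) -> None:
    iset.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_similarity_table(path: str | Path) -> SimilarityTable:
    """Read a TSV tau table with columns query, hit, tau (+ optional pert_type)."""
    df = pd.read_csv(path, sep="\t")
    return SimilarityTable(table=df)


def write_similarity_table(table: SimilarityTable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_tsv(df: pd.DataFrame, path: str | Path, float_format: str | None = None) -> None:
    """Write a result table as TSV with deterministic formatting."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format=float_format, na_rep="NA")
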