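"""Report shapes for the screen: count tables, gene lookups, network edges.

These functions aggregate screened correlation records into the publication
shapes of the analysis: a per-microRNA target-count table with per-group
totals, a per-gene lookup of correlated microRNAs split by predicting
database, and a bipartite (microRNA, gene) edge list for graph tools. A
hierarchical-clustering helper orders expression matrices for heat-map
display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "build_count_table",
    "count_targets",
    "distinct_gene_counts",
    "gene_lookup",
    "GeneLookupRow",
    "gene_lookup_table",
    "network_edges",
    "to_networkx",
    "cluster_heatmap_matrix",
]

logger = logging.getLogger(__name__)

TOTAL_LABEL = "Total"

COUNT_COLUMNS = ["mirna_id", "group", "count_targetscan", "count_mirbase", "count_shared"]
_SCOPE_TO_COLUMN = {
    "TARGETSCAN": "count_targetscan",
    "MIRBASE": "count_mirbase",
    "BOTH": "count_shared",
}


def _records_frame(obj) -> pd.DataFrame:
    """Accept a ScreenResult or a plain records DataFrame."""
    return obj.records if hasattr(obj, "records") else obj


def count_targets(
    results_by_scope: dict,
    groups: pd.DataFrame | dict | None = None,
    on_shared_violation: str = "warn",
) -> pd.DataFrame:
    """Distinct correlated genes per microRNA in each candidate scope.

    ``results_by_scope`` maps scope names (``TARGETSCAN``, ``MIRBASE``,
    ``BOTH``) to screen results or record frames. Group labels are taken
    from the records themselves unless ``groups`` overrides them.

    The bound ``count_shared <= min(count_targetscan, count_mirbase)`` is a
    theorem when every scope applies the same correlation-strength filters,
    but each scope adjusts p values within its own BH family, and the
    smaller intersection family can admit a pair that a single-database
    family rejects. ``on_shared_violation`` controls whether such rows
    ``"warn"`` (default) or ``"raise"``.
    """
    if isinstance(groups, pd.DataFrame):
        group_of = dict(zip(groups["mirna_id"], groups["group"]))
    else:
        group_of = dict(groups or {})
    per_scope = {}
    for scope, result in results_by_scope.items():
        records = _records_frame(result)
        if scope not in _SCOPE_TO_COLUMN:
            raise KeyError(f"unknown scope {scope!r}")
        if len(records):
            counts = records.groupby("mirna_id")["gene_id"].nunique()
            if "group" in records.columns:
                for mirna, grp in zip(records["mirna_id"], records["group"]):
                    group_of.setdefault(mirna, grp)
        else:
            counts = pd.Series(dtype=int)
        per_scope[_SCOPE_TO_COLUMN[scope]] = counts
    table = pd.DataFrame(per_scope).fillna(0).astype(int)
    table.index.name = "mirna_id"
    table = table.reset_index()
    for column in _SCOPE_TO_COLUMN.values():
        if column not in table.columns:
            table[column] = 0
    table["group"] = table["mirna_id"].map(group_of)
    table = table[COUNT_COLUMNS]
    bad = table[table["count_shared"] > table[["count_targetscan", "count_mirbase"]].min(axis=1)]
    if len(bad):
        message = (
            f"shared counts exceed a per-source count for {list(bad['mirna_id'])}"
            " (independent per-scope BH families)"
        )
        if on_shared_violation == "raise":
            raise ValueError(message)
        logger.warning(message)
    return table.sort_values(
        ["group", "count_shared"], ascending=[True, False]
    ).reset_index(drop=True)


def build_count_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Append a per-group ``Total`` row (column sums) to a count table.

    ``counts`` must have the per-microRNA columns produced by
    :func:`count_targets` (or an externally tabulated table of the same
    shape). The totals row of each group sums each count column over that
    group's microRNAs — the published-table convention, which counts
    (microRNA, gene) matches, not distinct genes; see
    :func:`distinct_gene_counts` for the latter.
    """
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"count table is missing columns: {missing}")
    if counts.empty:
        return counts[COUNT_COLUMNS].copy()
    blocks = []
    for group, sub in counts.groupby("group", sort=True):
        sub = sub.copy()
        total = {
            "mirna_id": TOTAL_LABEL,
            "group": group,
            "count_targetscan": int(sub["count_targetscan"].sum()),
            "count_mirbase": int(sub["count_mirbase"].sum()),
            "count_shared": int(sub["count_shared"].sum()),
        }
        blocks.append(pd.concat([sub, pd.DataFrame([total])], ignore_index=True))
    return pd.concat(blocks, ignore_index=True)[COUNT_COLUMNS]


def distinct_gene_counts(results_by_scope: dict) -> dict[str, int]:
    """Distinct genes per scope across all records (the prose convention)."""
    return {
        scope: int(_records_frame(result)["gene_id"].nunique())
        for scope, result in results_by_scope.items()
    }


@dataclass
class GeneLookupRow:
    """Correlated microRNAs of one candidate gene, split by database."""

    gene_id: str
    mirnas_by_source: dict[str, list[tuple[str, str]]]  # source -> [(mirna, group)]

    @property
    def n_mirnas(self) -> int:
        return len({m for pairs in self.mirnas_by_source.values() for m, _ in pairs})


def gene_lookup(records: pd.DataFrame, gene_list) -> list[GeneLookupRow]:
    """Per-gene listing of negatively correlated microRNAs by source.

    ``records`` needs ``mirna_id``, ``gene_id``, ``group`` and a per-record
    ``source`` (or ``sources``) column. Genes are matched case-insensitively
    against ``gene_list``; genes without any record get an empty row (they
    are reported, not dropped).
    """
    source_col = "source" if "source" in records.columns else "sources"
    by_gene: dict[str, dict[str, list[tuple[str, str]]]] = {}
    for _, rec in records.iterrows():
        key = str(rec["gene_id"]).upper()
        sources = str(rec[source_col]).split("+")
        for source in sources:
            by_gene.setdefault(key, {}).setdefault(source, [])
            entry = (rec["mirna_id"], rec.get("group", ""))
            if entry not in by_gene[key][source]:
                by_gene[key][source].append(entry)
    rows = []
    for gene in gene_list:
        rows.append(
            GeneLookupRow(gene_id=gene, mirnas_by_source=by_gene.get(str(gene).upper(), {}))
        )
    return rows


def gene_lookup_table(rows: list[GeneLookupRow], sources=("MIRBASE", "TARGETSCAN")) -> pd.DataFrame:
    """Render lookup rows as a delimited-friendly table; ``0`` marks no hit."""
    out = []
    for row in rows:
        rendered = {"gene_id": row.gene_id}
        for source in sources:
            hits = row.mirnas_by_source.get(source, [])
            rendered[source.lower()] = (
                "; ".join(f"{m} ({g})" for m, g in hits) if hits else "0"
            )
        out.append(rendered)
    return pd.DataFrame(out)


def network_edges(records) -> pd.DataFrame:
    """Bipartite (microRNA, gene) edges from screened records.

    Accepts one record frame or a scope->result mapping; duplicate pairs
    across scopes merge into one edge whose ``sources`` attribute joins the
    contributing databases.
    """
    if isinstance(records, dict):
        frames = []
        for result in records.values():
            frame = _records_frame(result)
            if len(frame):
                frames.append(frame)
        merged = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["mirna_id", "gene_id", "group", "r", "sources"])
        )
    else:
        merged = _records_frame(records)
    if not len(merged):
        return pd.DataFrame(columns=["mirna_id", "gene_id", "group", "r", "sources"])

    def merge_sources(values) -> str:
        parts = sorted({p for v in values for p in str(v).split("+")})
        return "+".join(parts)

    edges = (
        merged.groupby(["mirna_id", "gene_id"], sort=True)
        .agg(
            group=("group", "first"),
            r=("r", "first"),
            sources=("sources", merge_sources),
        )
        .reset_index()
    )
    return edges


def to_networkx(edges: pd.DataFrame):
    """Build a bipartite networkx graph from an edge list."""
    import networkx as nx

    graph = nx.Graph()
    for _, edge in edges.iterrows():
        graph.add_node(edge["mirna_id"], kind="mirna", group=edge.get("group"))
        graph.add_node(edge["gene_id"], kind="gene")
        graph.add_edge(
            edge["mirna_id"],
            edge["gene_id"],
            r=edge.get("r"),
            sources=edge.get("sources"),
        )
    return graph


def cluster_heatmap_matrix(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[int]]:
    """Order matrix rows by average-linkage clustering on correlation distance.

    Returns the reordered matrix and the dendrogram leaf order. Rendering is
    left to the caller; single-row matrices come back unchanged.
    """
    if len(matrix) < 2:
        return matrix.copy(), list(range(len(matrix)))
    values = matrix.to_numpy(dtype=float)
    distance = pdist(values, metric="correlation")
    # guard against tiny negative distances from floating-point round-off
    distance = np.clip(distance, 0.0, None)
    linkage = hierarchy.linkage(distance, method="average")
    order = list(hierarchy.leaves_list(linkage))
    return matrix.iloc[order], order
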