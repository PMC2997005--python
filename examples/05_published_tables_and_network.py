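"""Reporting shapes on the packaged published tables.

Rebuilds the per-microRNA target-count totals, looks pancreatic-development
genes up against their correlated microRNAs, and emits the bipartite
network edge list.
"""

from pancmir import build_count_table, gene_lookup, gene_lookup_table, network_edges
from pancmir.datasets import (
    load_development_genes,
    load_published_gene_mirnas,
    load_published_target_counts,
)
from pancmir.report import TOTAL_LABEL

table = build_count_table(load_published_target_counts())
totals = table[table["mirna_id"] == TOTAL_LABEL].set_index("group")
print("count-table totals (targetscan / mirbase / shared):")
for group in ("I", "II"):
    row = totals.loc[group]
    print(f"  Group {group}: {row['count_targetscan']} / "
          f"{row['count_mirbase']} / {row['count_shared']}")
print(f"shared pairs across both groups: {int(totals['count_shared'].sum())}")

records = load_published_gene_mirnas().rename(columns={"source": "sources"})
rows = gene_lookup(records, load_development_genes())
hits = [r for r in rows if r.mirnas_by_source]
print(f"\ndevelopment genes with >=1 negatively correlated microRNA: "
      f"{len(hits)}/{len(rows)}")
print(gene_lookup_table(hits[:4]).to_string(index=False))

edges = network_edges(records.assign(r=float("nan")))
print(f"\nnetwork: {len(edges)} edges, "
      f"{edges['mirna_id'].nunique()} microRNAs, {edges['gene_id'].nunique()} genes")

# Group I totals are the column sums of its four microRNA rows; a gene
# listed under several microRNAs is a candidate node of combinatorial
# regulation in the bipartite network.
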