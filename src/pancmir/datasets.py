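"""Packaged reference tables from the published fetal-pancreas analysis.

Three small fixtures ship with the package:

* the 212-microRNA trend-group table (4 increasing, 35 decreasing, 173
  unchanged);
* the per-microRNA correlated-target counts for the two prediction
  databases and their intersection;
* the lookup of 28 pancreatic-development candidate genes against the
  microRNAs that negatively correlate with them, split by database.

MicroRNA names are normalized on load so they join with parser output.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .predictions import normalize_mirna_name

__all__ = [
    "load_published_groups",
    "load_published_target_counts",
    "load_published_gene_mirnas",
    "load_development_genes",
]


def _data_path(name: str):
    return resources.files("pancmir").joinpath("data", name)


def load_published_groups() -> pd.DataFrame:
    """The published trend-group assignment (mirna_id, group)."""
    with resources.as_file(_data_path("mirna_groups.tsv")) as path:
        table = pd.read_csv(path, sep="\t")
    table["mirna_id"] = table["mirna_id"].map(normalize_mirna_name)
    return table


def load_published_target_counts() -> pd.DataFrame:
    """Per-microRNA correlated-target counts per database scope."""
    with resources.as_file(_data_path("target_counts.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def load_published_gene_mirnas() -> pd.DataFrame:
    """Long-form lookup: candidate gene, source database, microRNA, group."""
    with resources.as_file(_data_path("development_gene_mirnas.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def load_development_genes() -> list[str]:
    """The 28 pancreatic-development candidate genes, in published order."""
    with resources.as_file(_data_path("development_genes.txt")) as path:
        return [line.strip() for line in path.read_text().splitlines() if line.strip()]
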