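"""mRNA microarray expression: probe averaging and period binning.

The correlation screen consumes three-point per-gene stage profiles built
from already-normalized hybridization intensities: multi-probe genes are
averaged probe-wise first, then samples are averaged within each mRNA
gestational period. Because the periods partition the samples, the two
averaging steps commute.

The mRNA array periods (e.g. 9-11 / 15 / 20-23 wga) need not coincide with
the microRNA periods (10-11 / 13-15 / 21-22 wga); they are paired
positionally by :func:`align_period_schemes` and the window mismatch is
logged, not corrected.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .periods import PeriodScheme, period_means
from .predictions import normalize_gene_symbol

__all__ = [
    "average_probes",
    "bin_mrna_periods",
    "align_period_schemes",
    "load_probe_table",
    "load_probe_map",
]

logger = logging.getLogger(__name__)


def load_probe_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a delimited probe x sample intensity table (first column = probe id)."""
    table = pd.read_csv(path, sep=sep, index_col=0)
    return table.astype(float)


def load_probe_map(path, sep: str = "\t") -> pd.DataFrame:
    """Read a two-column probe -> gene map."""
    table = pd.read_csv(path, sep=sep, dtype=str)
    table.columns = ["probe_id", "gene_id"][: len(table.columns)]
    return table


def average_probes(
    probe_matrix: pd.DataFrame, probe_to_gene: pd.DataFrame | dict
) -> pd.DataFrame:
    """Average multi-probe genes into a gene x sample intensity matrix.

    ``probe_to_gene`` maps probe id to a single gene symbol (DataFrame with
    ``probe_id``/``gene_id`` columns, or a plain dict). Probes without a
    mapping are dropped and logged; a probe mapped to two genes is an error.
    """
    if isinstance(probe_to_gene, dict):
        mapping = pd.DataFrame(
            {"probe_id": list(probe_to_gene), "gene_id": list(probe_to_gene.values())}
        )
    else:
        mapping = probe_to_gene[["probe_id", "gene_id"]].copy()
    mapping = mapping.dropna()
    if mapping.empty:
        raise ValueError("probe-to-gene mapping is empty")
    dup = mapping[mapping.duplicated("probe_id", keep=False)]
    if dup["probe_id"].nunique() and (
        dup.groupby("probe_id")["gene_id"].nunique() > 1
    ).any():
        bad = dup.groupby("probe_id")["gene_id"].nunique()
        raise ValueError(
            f"probes mapped to more than one gene: {list(bad[bad > 1].index)}"
        )
    mapping = mapping.drop_duplicates("probe_id")
    mapping["gene_id"] = mapping["gene_id"].map(normalize_gene_symbol)

    gene_of = mapping.set_index("probe_id")["gene_id"]
    unmapped = [p for p in probe_matrix.index if p not in gene_of.index]
    if unmapped:
        logger.info("dropping %d unmapped probes", len(unmapped))
    kept = probe_matrix.loc[probe_matrix.index.isin(gene_of.index)]
    if not np.isfinite(kept.to_numpy(dtype=float)).all():
        raise ValueError("non-finite intensity in probe table")
    genes = kept.groupby(gene_of.loc[kept.index].to_numpy()).mean()
    genes.index.name = "gene_id"
    return genes


def bin_mrna_periods(expr: pd.DataFrame, mrna_scheme: PeriodScheme) -> pd.DataFrame:
    """Per-period mean intensity per gene, columns in period order."""
    missing = [s for s in mrna_scheme.samples if s not in expr.columns]
    if missing:
        raise ValueError(f"scheme samples absent from expression table: {missing}")
    return period_means(expr, mrna_scheme)


def align_period_schemes(
    mirna_scheme: PeriodScheme, mrna_scheme: PeriodScheme
) -> list[tuple[str, str]]:
    """Pair the microRNA and mRNA periods positionally (1st with 1st, ...).

    The paired wga windows are logged so mismatched ranges (e.g. 13-15 wga
    against 15 wga) are visible in the run log.
    """
    if len(mirna_scheme) != len(mrna_scheme):
        raise ValueError(
            f"period count mismatch: {len(mirna_scheme)} microRNA vs "
            f"{len(mrna_scheme)} mRNA periods"
        )
    pairing = list(zip(mirna_scheme.names, mrna_scheme.names))
    for mirna_period, mrna_period in pairing:
        logger.info("aligned periods: %s <-> %s", mirna_period, mrna_period)
    return pairing
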