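"""Parsers for microRNA target-prediction database dumps.

Two dialects are supported: the TargetScan (v5-era) site context-score table
and the Sanger miRBase Targets / MicroCosm v5 dump. Both are reduced to
deduplicated, name-normalized (microRNA, gene symbol) pairs; site- and
transcript-level rows collapse to the gene level. The two sources can be
intersected, the screen's highest-confidence candidate scope.

Column layouts of the historical dumps drift between releases, so each parser
accepts a column-mapping override.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "PredictionSet",
    "MIRBASE",
    "TARGETSCAN",
    "normalize_mirna_name",
    "normalize_gene_symbol",
    "parse_targetscan",
    "parse_mirbase_targets",
    "intersect_predictions",
]

MIRBASE = "MIRBASE"
TARGETSCAN = "TARGETSCAN"

TARGETSCAN_COLUMNS = {
    "gene": "Gene Symbol",
    "mirna": "miRNA",
    "species": "Species ID",
}
MIRBASE_COLUMNS = {
    "mirna": "SEQ",
    "gene": "EXTERNAL_NAME",
    "transcript": "TRANSCRIPT_ID",
}

# a species code (hsa, mmu, dre, ...) only counts as a prefix when a
# miR/let stem follows, so "let-7g" itself is never stripped
_SPECIES_PREFIX = re.compile(r"^[a-z]{3,4}-(?=(mir|let)-)", re.IGNORECASE)
_MIR_PREFIX = re.compile(r"^mir(?=-)", re.IGNORECASE)


@dataclass
class PredictionSet:
    """Deduplicated (microRNA, gene) predicted-target pairs from one source.

    ``pairs`` has normalized ``mirna_id`` and ``gene_id`` columns; raw
    provenance fields (transcript ids, context scores) are kept when the
    dialect provides them but play no role in membership.
    """

    source: str
    pairs: pd.DataFrame
    normalization_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"mirna_id", "gene_id"}
        if not required.issubset(self.pairs.columns):
            raise ValueError("pairs must carry mirna_id and gene_id columns")
        if self.pairs[["mirna_id", "gene_id"]].duplicated().any():
            raise ValueError("pairs must be deduplicated")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def pair_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            zip(self.pairs["mirna_id"], self.pairs["gene_id"])
        )

    def per_mirna_counts(self) -> pd.Series:
        """Distinct predicted genes per microRNA."""
        return self.pairs.groupby("mirna_id")["gene_id"].nunique()

    def restrict_to(self, mirnas) -> "PredictionSet":
        """Pairs whose microRNA is in ``mirnas`` (already-normalized ids)."""
        keep = self.pairs["mirna_id"].isin(set(mirnas))
        return PredictionSet(self.source, self.pairs.loc[keep].reset_index(drop=True))


def normalize_mirna_name(raw: str) -> str:
    """Normalize a microRNA name for joining across platforms.

    Strips the species prefix (``hsa-`` and kin), case-folds the ``miR``
    stem, and preserves arm (-5p/-3p) and paralog (a/b, -1/-2) suffixes, so
    ``hsa-miR-17-5p`` and ``miR-17-5p`` join while ``miR-124a`` and
    ``miR-124b`` stay distinct.
    """
    if raw is None or not str(raw).strip():
        raise ValueError("empty microRNA name")
    name = str(raw).strip()
    name = _SPECIES_PREFIX.sub("", name)
    name = _MIR_PREFIX.sub("miR", name)
    if name.lower().startswith("let-"):
        name = "let-" + name[4:]
    return name


def normalize_gene_symbol(raw: str) -> str:
    """Upper-case, whitespace-stripped gene symbol."""
    if raw is None or not str(raw).strip():
        raise ValueError("empty gene symbol")
    return str(raw).strip().upper()


def _require_columns(table: pd.DataFrame, needed: dict[str, str], dialect: str) -> None:
    missing = [c for c in needed.values() if c not in table.columns]
    if missing:
        raise ValueError(f"{dialect} table is missing required columns: {missing}")


def _apply_symbol_map(genes: pd.Series, symbol_map: dict[str, str] | None) -> pd.Series:
    if not symbol_map:
        return genes
    mapped = {normalize_gene_symbol(k): normalize_gene_symbol(v) for k, v in symbol_map.items()}
    return genes.map(lambda g: mapped.get(g, g))


def parse_targetscan(
    path,
    species: int | str | None = 9606,
    column_map: dict[str, str] | None = None,
    symbol_map: dict[str, str] | None = None,
) -> PredictionSet:
    """Parse a TargetScan site context-score dump into a pair set.

    Rows are filtered to ``species`` (NCBI taxon id, default human 9606;
    None disables the filter) and the per-site rows collapse to one pair per
    (microRNA, gene symbol). Context scores are kept as provenance only —
    no score cutoff is applied.
    """
    cols = {**TARGETSCAN_COLUMNS, **(column_map or {})}
    table = pd.read_csv(path, sep="\t", dtype=str, compression="infer")
    _require_columns(table, cols, "TargetScan")
    log: list[str] = []
    if species is not None:
        before = len(table)
        table = table[table[cols["species"]].astype(str) == str(species)]
        log.append(f"species filter {species}: {before} -> {len(table)} rows")
    pairs = pd.DataFrame(
        {
            "mirna_id": table[cols["mirna"]].map(normalize_mirna_name),
            "gene_id": _apply_symbol_map(
                table[cols["gene"]].map(normalize_gene_symbol), symbol_map
            ),
        }
    )
    pairs = pairs.drop_duplicates().sort_values(["mirna_id", "gene_id"]).reset_index(drop=True)
    log.append(f"{len(pairs)} unique pairs")
    return PredictionSet(TARGETSCAN, pairs, log)


def parse_mirbase_targets(
    path,
    column_map: dict[str, str] | None = None,
    symbol_map: dict[str, str] | None = None,
) -> PredictionSet:
    """Parse a miRBase Targets / MicroCosm v5 dump into a pair set.

    Transcript-level target rows collapse to the gene level via the
    external gene symbol column; an optional ``symbol_map`` translates
    symbols that drifted between annotation eras (identity by default).
    """
    cols = {**MIRBASE_COLUMNS, **(column_map or {})}
    table = pd.read_csv(
        path, sep="\t", dtype=str, comment=None, compression="infer"
    )
    # MicroCosm dumps sometimes prefix the header line with '##'
    if table.columns[0].startswith("#"):
        table = table.rename(columns={table.columns[0]: table.columns[0].lstrip("#")})
    _require_columns(table, cols, "miRBase Targets")
    pairs = pd.DataFrame(
        {
            "mirna_id": table[cols["mirna"]].map(normalize_mirna_name),
            "gene_id": _apply_symbol_map(
                table[cols["gene"]].map(normalize_gene_symbol), symbol_map
            ),
        }
    )
    pairs = pairs.drop_duplicates().sort_values(["mirna_id", "gene_id"]).reset_index(drop=True)
    return PredictionSet(MIRBASE, pairs, [f"{len(pairs)} unique pairs"])


def intersect_predictions(a: PredictionSet, b: PredictionSet) -> PredictionSet:
    """Pairs predicted by both sources (symmetric; tagged with both names)."""
    shared = a.pair_set & b.pair_set
    pairs = (
        pd.DataFrame(sorted(shared), columns=["mirna_id", "gene_id"])
        if shared
        else pd.DataFrame(columns=["mirna_id", "gene_id"])
    )
    source = "+".join(sorted({a.source, b.source}))
    return PredictionSet(source, pairs)
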