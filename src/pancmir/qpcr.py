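"""qPCR-array ingestion and relative quantification.

Ct (cycle threshold) tables from TaqMan low-density arrays are read into a
:class:`CtMatrix`, normalized to an endogenous-control small RNA by
``RQ = 2^-dCt`` (:func:`compute_rq`), binned into gestational periods and
filtered by a per-period detection quorum (:func:`apply_detection_quorum`).

Cells at or above the undetermined threshold (default 35 cycles), or carrying
the literal token ``Undetermined``, are treated as missing throughout; a
missing Ct propagates to a missing RQ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .periods import PeriodScheme, period_means

__all__ = [
    "CtMatrix",
    "RQMatrix",
    "QuorumResult",
    "read_ct_table",
    "write_ct_table",
    "compute_rq",
    "assign_periods",
    "apply_detection_quorum",
    "mirna_period_profiles",
]

logger = logging.getLogger(__name__)

UNDETERMINED_TOKEN = "Undetermined"
DEFAULT_UNDETERMINED_THRESHOLD = 35.0

# header keywords that identify the orientation of a Ct file
_MIRNA_ROW_KEYWORDS = ("mirna", "microrna", "mir", "assay", "detector", "target")
_SAMPLE_ROW_KEYWORDS = ("sample", "specimen", "tissue")


@dataclass
class CtMatrix:
    """Cycle-threshold values, microRNAs as rows and samples as columns.

    Undetermined wells are stored as NaN. The endogenous-control row
    (``control_id``) must be present and determined in every sample.
    """

    ct: pd.DataFrame
    control_id: str

    def __post_init__(self) -> None:
        if self.control_id not in self.ct.index:
            raise ValueError(
                f"endogenous control {self.control_id!r} missing from Ct table"
            )
        control = self.ct.loc[self.control_id]
        if control.isna().any():
            bad = list(control.index[control.isna()])
            raise ValueError(
                f"control {self.control_id!r} undetermined in samples {bad}"
            )
        values = self.ct.to_numpy(dtype=float)
        determined = ~np.isnan(values)
        if not np.isfinite(values[determined]).all():
            raise ValueError("non-finite Ct value in table")
        if (values[determined] < 0).any():
            raise ValueError("negative Ct value in table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.ct.index)


@dataclass
class RQMatrix:
    """Relative quantification (2^-dCt) values; control row removed.

    ``period_of_sample`` is populated by :func:`assign_periods`.
    """

    rq: pd.DataFrame
    period_of_sample: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = self.rq.to_numpy(dtype=float)
        present = ~np.isnan(values)
        if (values[present] <= 0).any():
            raise ValueError("RQ values must be positive where present")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rq.columns)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.rq.index)


@dataclass
class QuorumResult:
    """Outcome of the detection-quorum filter."""

    retained: RQMatrix
    log: pd.DataFrame  # per miRNA: detected counts per period, retained flag


class CtParseError(ValueError):
    """A cell of a Ct table could not be parsed."""


def _parse_cell(raw: object, threshold: float, row: str, col: str) -> float:
    if isinstance(raw, str):
        token = raw.strip()
        if token.lower() == UNDETERMINED_TOKEN.lower():
            return np.nan
        try:
            value = float(token)
        except ValueError:
            raise CtParseError(
                f"cell ({row!r}, {col!r}): cannot parse {raw!r} as a Ct value"
            ) from None
    elif raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    else:
        value = float(raw)
    if value < 0:
        raise CtParseError(f"cell ({row!r}, {col!r}): negative Ct {value}")
    return np.nan if value >= threshold else value


def _detect_orientation(table: pd.DataFrame, control_id: str) -> bool:
    """Return True when rows are microRNAs (the canonical orientation)."""
    header = (table.index.name or "").strip().lower()
    if header:
        if any(k in header for k in _SAMPLE_ROW_KEYWORDS):
            return False
        if any(k in header for k in _MIRNA_ROW_KEYWORDS):
            return True
    in_rows = control_id in table.index
    in_cols = control_id in table.columns
    if in_rows == in_cols:
        raise ValueError(
            "cannot determine table orientation: header gives no keyword and "
            f"control {control_id!r} is "
            + ("in both rows and columns" if in_rows else "absent")
        )
    return in_rows


def read_ct_table(
    path,
    control_id: str = "RNU48",
    undetermined_threshold: float = DEFAULT_UNDETERMINED_THRESHOLD,
    sep: str | None = None,
) -> CtMatrix:
    """Read a delimited Ct table into a :class:`CtMatrix`.

    Orientation (microRNAs as rows vs columns) is auto-detected from the
    header keyword of the index column, falling back to the position of the
    control row; ambiguous files are rejected. Cells holding the literal
    token ``Undetermined`` or a value at or above ``undetermined_threshold``
    become missing.
    """
    table = pd.read_csv(path, sep=sep, engine="python", index_col=0, dtype=str)
    table.index = table.index.astype(str).str.strip()
    table.columns = table.columns.astype(str).str.strip()
    if not _detect_orientation(table, control_id):
        table = table.T
    raw = table.to_numpy(dtype=object)
    parsed_values = np.empty(raw.shape, dtype=float)
    for i, row in enumerate(table.index):
        for j, col in enumerate(table.columns):
            parsed_values[i, j] = _parse_cell(
                raw[i, j], undetermined_threshold, row, col
            )
    parsed = pd.DataFrame(parsed_values, index=table.index.copy(), columns=table.columns.copy())
    parsed.index.name = "miRNA"
    parsed.columns.name = None
    if control_id not in parsed.index:
        raise ValueError(
            f"endogenous control {control_id!r} missing from Ct table"
        )
    if (parsed.index == control_id).sum() > 1:
        # replicate control wells: average their Ct per sample
        logger.info("averaging replicate control rows for %s", control_id)
        control_mean = parsed.loc[[control_id]].mean(axis=0)
        parsed = parsed.loc[parsed.index != control_id]
        parsed.loc[control_id] = control_mean
    return CtMatrix(ct=parsed, control_id=control_id)


def write_ct_table(ct: CtMatrix, path, sep: str = "\t") -> None:
    """Write a Ct table; missing cells become the ``Undetermined`` token.

    Determined values are written with full float precision so a
    read/write round trip is bit-exact.
    """
    out = ct.ct.map(lambda v: UNDETERMINED_TOKEN if pd.isna(v) else repr(float(v)))
    out.index.name = "miRNA"
    out.to_csv(path, sep=sep)


def compute_rq(ct: CtMatrix) -> RQMatrix:
    """Relative quantification against the endogenous control.

    For each sample ``s`` and microRNA ``m``:
    ``dCt = Ct(m, s) - Ct(control, s)`` and ``RQ = 2^-dCt``. Missing Ct
    propagates to missing RQ; the control row (RQ identically 1 against
    itself) is dropped from the output.
    """
    control = ct.ct.loc[ct.control_id]
    delta = ct.ct.sub(control, axis=1)
    rq = np.exp2(-delta)
    # the control against itself is exactly 1 by construction
    assert (rq.loc[ct.control_id] == 1.0).all()
    rq = rq.drop(index=ct.control_id)
    return RQMatrix(rq=rq)


def assign_periods(rq: RQMatrix, scheme: PeriodScheme) -> RQMatrix:
    """Attach the period of each sample; reorder samples to period order."""
    mapping = scheme.sample_to_period
    unassigned = [s for s in rq.sample_ids if s not in mapping]
    if unassigned:
        raise ValueError(f"samples not assigned to any period: {unassigned}")
    absent = [s for s in scheme.samples if s not in rq.sample_ids]
    if absent:
        raise ValueError(f"scheme samples absent from RQ table: {absent}")
    ordered = rq.rq[scheme.samples]
    return RQMatrix(rq=ordered, period_of_sample=dict(mapping))


def apply_detection_quorum(rq: RQMatrix, scheme: PeriodScheme) -> QuorumResult:
    """Keep microRNAs meeting the detection quorum in *every* period.

    An assay counts as detected in a sample when its RQ is present (the
    source Ct was determined). The returned log records the per-period
    detection counts and quorum for every microRNA, retained or not.
    """
    if not rq.period_of_sample:
        raise ValueError("periods not assigned; call assign_periods first")
    detected = rq.rq.notna()
    rows = {}
    keep = pd.Series(True, index=rq.rq.index)
    for period in scheme:
        counts = detected[list(period.samples)].sum(axis=1)
        rows[f"detected_{period.name}"] = counts
        rows[f"required_{period.name}"] = period.min_detected
        keep &= counts >= period.min_detected
    log = pd.DataFrame(rows, index=rq.rq.index)
    log["retained"] = keep
    excluded = log.index[~keep]
    if len(excluded):
        logger.info("quorum filter excluded %d microRNAs", len(excluded))
    retained = RQMatrix(
        rq=rq.rq.loc[keep], period_of_sample=dict(rq.period_of_sample)
    )
    return QuorumResult(retained=retained, log=log)


def mirna_period_profiles(rq: RQMatrix, scheme: PeriodScheme) -> pd.DataFrame:
    """Per-period mean RQ profile for every microRNA (rows) in period order."""
    return period_means(rq.rq, scheme)
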