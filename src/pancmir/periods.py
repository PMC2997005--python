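"""Gestational-period schemes and per-period aggregation.

A :class:`PeriodScheme` partitions the study's samples into ordered
developmental windows (here: weeks of gestational age, wga). Each period
carries a detection quorum — the minimum number of samples in which an assay
must amplify for the assay to count as expressed in that period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["Period", "PeriodScheme", "period_means"]


@dataclass(frozen=True)
class Period:
    """One ordered developmental window.

    Parameters
    ----------
    name
        Label of the window, e.g. ``"10-11wga"``.
    samples
        Sample identifiers belonging to this window.
    min_detected
        Detection quorum: assays must amplify in at least this many of the
        period's samples to be considered expressed here.
    """

    name: str
    samples: tuple[str, ...]
    min_detected: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        if len(set(self.samples)) != len(self.samples):
            raise ValueError(f"period {self.name!r} lists a sample twice")
        if not self.samples:
            raise ValueError(f"period {self.name!r} has no samples")
        if not (0 <= self.min_detected <= len(self.samples)):
            raise ValueError(
                f"period {self.name!r}: quorum {self.min_detected} out of "
                f"{len(self.samples)} samples is infeasible"
            )

    @property
    def quorum(self) -> tuple[int, int]:
        """(min detected, total samples) pair."""
        return (self.min_detected, len(self.samples))


@dataclass
class PeriodScheme:
    """Ordered partition of samples into developmental periods."""

    periods: list[Period] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.periods = list(self.periods)
        if not self.periods:
            raise ValueError("a period scheme needs at least one period")
        seen: dict[str, str] = {}
        for period in self.periods:
            for sample in period.samples:
                if sample in seen:
                    raise ValueError(
                        f"sample {sample!r} appears in periods "
                        f"{seen[sample]!r} and {period.name!r}"
                    )
                seen[sample] = period.name

    def __len__(self) -> int:
        return len(self.periods)

    def __iter__(self):
        return iter(self.periods)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.periods]

    @property
    def samples(self) -> list[str]:
        """All samples in period order."""
        return [s for p in self.periods for s in p.samples]

    @property
    def sample_to_period(self) -> dict[str, str]:
        return {s: p.name for p in self.periods for s in p.samples}

    def period(self, name: str) -> Period:
        for p in self.periods:
            if p.name == name:
                return p
        raise KeyError(name)


def period_means(values: pd.DataFrame, scheme: PeriodScheme) -> pd.DataFrame:
    """Average a (entity x sample) table within each period.

    Missing values are ignored; a period mean is missing only when every
    sample of that period is missing for the entity. Columns of the result
    follow the scheme's period order.
    """
    out = {}
    for period in scheme:
        missing = [s for s in period.samples if s not in values.columns]
        if missing:
            raise KeyError(
                f"period {period.name!r}: samples {missing} absent from table"
            )
        out[period.name] = values[list(period.samples)].mean(axis=1, skipna=True)
    return pd.DataFrame(out, index=values.index)
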