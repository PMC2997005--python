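"""End-to-end convenience runner: Ct table to screened target candidates.

Chains the stages in study order — relative quantification, period
assignment, detection quorum, trend classification, probe averaging and
period binning, then the per-scope anti-correlation screen — and bundles
every intermediate in a :class:`PipelineResult`. Intended for scripted runs
and the examples; each stage remains usable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import classify, expression, qpcr, report, screen
from .periods import PeriodScheme
from .predictions import PredictionSet
from .qpcr import CtMatrix

__all__ = ["PipelineResult", "run_study"]


@dataclass
class PipelineResult:
    """Everything one run computes, stage by stage."""

    rq: qpcr.RQMatrix
    quorum: qpcr.QuorumResult
    tests: pd.DataFrame
    groups: pd.DataFrame
    mirna_profiles: pd.DataFrame
    gene_profiles: pd.DataFrame
    scopes: dict[str, screen.ScreenResult]
    counts: pd.DataFrame
    edges: pd.DataFrame
    period_pairing: list[tuple[str, str]] = field(default_factory=list)

    @property
    def screened_pairs(self) -> dict[str, frozenset]:
        """(microRNA, gene) pair set reported per scope."""
        return {
            scope: frozenset(
                zip(res.records["mirna_id"], res.records["gene_id"])
            )
            for scope, res in self.scopes.items()
        }


def run_study(
    ct: CtMatrix,
    mirna_scheme: PeriodScheme,
    probe_matrix: pd.DataFrame,
    probe_map,
    mrna_scheme: PeriodScheme,
    pred_mirbase: PredictionSet,
    pred_targetscan: PredictionSet,
    config: screen.ScreenConfig | None = None,
    alpha: float = 0.05,
) -> PipelineResult:
    """Run the full analysis on one study's inputs."""
    rq = qpcr.assign_periods(qpcr.compute_rq(ct), mirna_scheme)
    quorum = qpcr.apply_detection_quorum(rq, mirna_scheme)
    tests = classify.pairwise_ttests(quorum.retained, mirna_scheme)
    groups = classify.classify_groups(tests, alpha=alpha)

    pairing = expression.align_period_schemes(mirna_scheme, mrna_scheme)
    mirna_profiles = qpcr.mirna_period_profiles(quorum.retained, mirna_scheme)
    gene_matrix = expression.average_probes(probe_matrix, probe_map)
    gene_profiles = expression.bin_mrna_periods(gene_matrix, mrna_scheme)

    scopes = screen.run_scopes(
        mirna_profiles, gene_profiles, pred_mirbase, pred_targetscan, groups, config
    )
    counts = report.build_count_table(report.count_targets(scopes, groups))
    edges = report.network_edges(scopes)
    return PipelineResult(
        rq=rq,
        quorum=quorum,
        tests=tests,
        groups=groups,
        mirna_profiles=mirna_profiles,
        gene_profiles=gene_profiles,
        scopes=scopes,
        counts=counts,
        edges=edges,
        period_pairing=pairing,
    )
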