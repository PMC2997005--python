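"""Anti-correlation screen between microRNA and predicted-target profiles.

For every algorithm-predicted (microRNA, gene) pair whose microRNA changes
during development (Group I or II), the Pearson correlation between the
microRNA's per-period RQ profile and the gene's per-period intensity profile
is computed, with a two-sided p value for H0: r = 0 from the t transform
``t = r * sqrt((n - 2) / (1 - r^2))`` on ``n - 2`` degrees of freedom.
Raw p values are Benjamini-Hochberg adjusted within the run's candidate
family, and the screen keeps strongly negative correlations:
``r < 0`` and ``r^2 >= 0.8`` (both thresholds configurable), with the
adjusted-p cut as a toggle.

Each candidate scope (miRBase alone, TargetScan alone, their intersection)
forms its own run and hence its own adjustment family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .predictions import PredictionSet

__all__ = [
    "ScreenConfig",
    "ScreenResult",
    "pearson_r",
    "correlation_pvalue",
    "bh_adjust",
    "run_screen",
    "run_scopes",
]

logger = logging.getLogger(__name__)

SCREEN_GROUPS = ("I", "II")


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and toggles of the anti-correlation screen.

    ``r_squared_min`` is the primary strength criterion (default 0.8);
    ``require_negative`` keeps suppressive correlations only;
    ``use_adjusted_p``/``alpha_adj`` control the BH-adjusted significance
    cut. With three-point profiles (one degree of freedom) the raw p only
    reaches below 0.05 for |r| > 0.997, so the adjusted-p cut is near-
    vacuous except at |r| ~ 1; it can be disabled to screen on r^2 alone.
    """

    r_squared_min: float = 0.8
    alpha_adj: float = 0.05
    require_negative: bool = True
    use_adjusted_p: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.r_squared_min <= 1:
            raise ValueError("r_squared_min must lie in (0, 1]")
        if not 0 < self.alpha_adj <= 1:
            raise ValueError("alpha_adj must lie in (0, 1]")


@dataclass
class ScreenResult:
    """Outcome of one screen run (one candidate scope)."""

    records: pd.DataFrame          # pairs passing every enabled filter
    candidates: pd.DataFrame       # every scored candidate pair
    skipped: pd.DataFrame          # pairs not scored, with reasons
    config: ScreenConfig = field(default_factory=ScreenConfig)
    scope: str = ""

    @property
    def manifest(self) -> dict:
        """Counts at each filter stage, for the run log."""
        c = self.candidates
        cfg = self.config
        negative = c["r"] < 0 if len(c) else pd.Series(dtype=bool)
        return {
            "scope": self.scope,
            "family_size": int(len(c)),
            "skipped": int(len(self.skipped)),
            "negative": int(negative.sum()) if len(c) else 0,
            "pass_r_squared": int(
                ((c["r_squared"] >= cfg.r_squared_min) & negative).sum()
            )
            if len(c)
            else 0,
            "reported": int(len(self.records)),
            "config": {
                "r_squared_min": cfg.r_squared_min,
                "alpha_adj": cfg.alpha_adj,
                "require_negative": cfg.require_negative,
                "use_adjusted_p": cfg.use_adjusted_p,
            },
        }


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length profiles.

    Returns NaN (undefined-correlation marker) when either profile has zero
    variance; callers skip and log such pairs rather than treating them as
    uncorrelated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return np.nan
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def correlation_pvalue(r: float, n_points: int) -> float:
    """Two-sided p for H0: r = 0 via the t transform on n - 2 df.

    |r| = 1 returns p = 0 (limit convention).
    """
    if n_points < 3:
        raise ValueError("need at least 3 points")
    if not -1 <= r <= 1:
        raise ValueError("correlation outside [-1, 1]")
    if abs(r) == 1:
        return 0.0
    df = n_points - 2
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order.

    Sort ascending, scale p_(i) by m/i, enforce monotonicity from the
    largest rank down, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _score_pairs(
    mirna_profiles: pd.DataFrame,
    gene_profiles: pd.DataFrame,
    pairs: pd.DataFrame,
) -> np.ndarray:
    """Vectorized Pearson r over candidate pairs of equal-length profiles."""
    x = mirna_profiles.loc[pairs["mirna_id"]].to_numpy(dtype=float)
    y = gene_profiles.loc[pairs["gene_id"]].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc * xc).sum(axis=1) * (yc * yc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc * yc).sum(axis=1) / denom, np.nan)
    return np.clip(r, -1.0, 1.0)


def run_screen(
    mirna_profiles: pd.DataFrame,
    gene_profiles: pd.DataFrame,
    predictions: PredictionSet,
    groups: pd.DataFrame | dict,
    config: ScreenConfig | None = None,
    scope: str | None = None,
) -> ScreenResult:
    """Screen one candidate scope for strong negative correlations.

    Parameters
    ----------
    mirna_profiles, gene_profiles
        Per-period mean profiles (rows = entities, columns = aligned
        periods, same column count).
    predictions
        Candidate (microRNA, gene) pairs; only predicted pairs are ever
        scored or reported.
    groups
        Trend assignment per microRNA (``classify_groups`` frame or a
        mapping); only Group I and II microRNAs enter the screen.
    """
    config = config or ScreenConfig()
    if mirna_profiles.shape[1] != gene_profiles.shape[1]:
        raise ValueError("profile period counts differ; align the schemes first")
    n_points = mirna_profiles.shape[1]
    if isinstance(groups, pd.DataFrame):
        group_of = dict(zip(groups["mirna_id"], groups["group"]))
    else:
        group_of = dict(groups)

    pairs = predictions.pairs[["mirna_id", "gene_id"]].copy()
    pairs["group"] = pairs["mirna_id"].map(group_of)
    skip_reason = pd.Series("", index=pairs.index)
    skip_reason[~pairs["group"].isin(SCREEN_GROUPS)] = "mirna not in group I/II"
    missing_mirna = ~pairs["mirna_id"].isin(mirna_profiles.index)
    skip_reason[missing_mirna & (skip_reason == "")] = "mirna profile missing"
    missing_gene = ~pairs["gene_id"].isin(gene_profiles.index)
    skip_reason[missing_gene & (skip_reason == "")] = "gene profile missing"
    profile_na = pd.Series(False, index=pairs.index)
    scorable = skip_reason == ""
    if scorable.any():
        sub = pairs.loc[scorable]
        x_na = mirna_profiles.loc[sub["mirna_id"]].isna().any(axis=1).to_numpy()
        y_na = gene_profiles.loc[sub["gene_id"]].isna().any(axis=1).to_numpy()
        profile_na.loc[scorable] = x_na | y_na
    skip_reason[profile_na] = "profile has missing period mean"

    candidates = pairs.loc[skip_reason == ""].reset_index(drop=True)
    r = _score_pairs(mirna_profiles, gene_profiles, candidates) if len(candidates) else np.array([])
    zero_var = np.isnan(r)
    if zero_var.any():
        degenerate = candidates.loc[zero_var, ["mirna_id", "gene_id", "group"]].copy()
        degenerate["reason"] = "zero-variance profile"
    else:
        degenerate = pd.DataFrame(columns=["mirna_id", "gene_id", "group", "reason"])
    candidates = candidates.loc[~zero_var].reset_index(drop=True)
    r = r[~zero_var]

    candidates["r"] = r
    candidates["r_squared"] = r ** 2
    candidates["n_points"] = n_points
    candidates["p_raw"] = [correlation_pvalue(v, n_points) for v in r]
    candidates["p_adj"] = (
        bh_adjust(candidates["p_raw"].to_numpy()) if len(candidates) else np.nan
    )
    candidates["sources"] = predictions.source

    keep = pd.Series(True, index=candidates.index)
    if config.require_negative:
        keep &= candidates["r"] < 0
    keep &= candidates["r_squared"] >= config.r_squared_min
    if config.use_adjusted_p:
        keep &= candidates["p_adj"] < config.alpha_adj
    records = candidates.loc[keep].reset_index(drop=True)

    skipped = pairs.loc[skip_reason != "", ["mirna_id", "gene_id", "group"]].copy()
    skipped["reason"] = skip_reason[skip_reason != ""].to_numpy()
    skipped = pd.concat([skipped, degenerate], ignore_index=True)
    if len(skipped):
        logger.info("screen skipped %d candidate pairs", len(skipped))

    return ScreenResult(
        records=records,
        candidates=candidates,
        skipped=skipped,
        config=config,
        scope=scope or predictions.source,
    )


def run_scopes(
    mirna_profiles: pd.DataFrame,
    gene_profiles: pd.DataFrame,
    pred_mirbase: PredictionSet,
    pred_targetscan: PredictionSet,
    groups: pd.DataFrame | dict,
    config: ScreenConfig | None = None,
) -> dict[str, ScreenResult]:
    """Run the screen per database and on the intersection.

    Returns results keyed ``"MIRBASE"``, ``"TARGETSCAN"`` and ``"BOTH"``;
    each scope is an independent BH family.
    """
    from .predictions import intersect_predictions

    both = intersect_predictions(pred_mirbase, pred_targetscan)
    return {
        "MIRBASE": run_screen(
            mirna_profiles, gene_profiles, pred_mirbase, groups, config, scope="MIRBASE"
        ),
        "TARGETSCAN": run_screen(
            mirna_profiles, gene_profiles, pred_targetscan, groups, config, scope="TARGETSCAN"
        ),
        "BOTH": run_screen(
            mirna_profiles, gene_profiles, both, groups, config, scope="BOTH"
        ),
    }
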