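"""Developmental trend classification of microRNAs.

Every retained microRNA is tested between each ordered pair of gestational
periods with a two-tailed Student's t test on its per-sample RQ values
(pooled variance by default) and assigned to one of:

* Group I  — expression significantly increased on at least one transition;
* Group II — significantly decreased on at least one transition;
* Group III — no significant change anywhere;
* AMBIGUOUS — significant changes in both directions (no such case exists in
  the three-group scheme, so it is surfaced rather than silently assigned).

Significance is strict ``p < alpha``; no multiple-testing correction is
applied at this stage (correction belongs to the downstream correlation
screen).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .periods import PeriodScheme
from .qpcr import RQMatrix

__all__ = ["pairwise_ttests", "classify_groups", "GROUP_LABELS"]

GROUP_LABELS = ("I", "II", "III", "AMBIGUOUS")


def _pooled_ttest(x: np.ndarray, y: np.ndarray, equal_var: bool) -> tuple[float, float]:
    """Two-tailed t test with degenerate-variance conventions.

    Zero variance in both samples: equal means give t = 0, p = 1 (no
    evidence of change); different means give p = 0 (the noise-free limit).
    """
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x[0] == y[0]:
            return 0.0, 1.0
        return np.inf * np.sign(y[0] - x[0]), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def pairwise_ttests(
    rq: RQMatrix,
    scheme: PeriodScheme,
    equal_var: bool = True,
    log_scale: bool = False,
) -> pd.DataFrame:
    """Test every microRNA between every ordered period pair.

    Parameters
    ----------
    rq
        Period-assigned (and typically quorum-filtered) RQ matrix.
    scheme
        The period scheme; for three periods this yields the three
        comparisons earlier-vs-later in period order.
    equal_var
        Pooled-variance Student's t (default) or Welch when False.
    log_scale
        Test log2(RQ) instead of raw RQ (off by default).

    Returns
    -------
    DataFrame with one row per (microRNA, period pair): the period means,
    the direction of change (sign of later minus earlier mean), the t
    statistic and two-tailed p value. Comparisons with fewer than two
    non-missing values on either side are marked untestable (``p`` missing).
    """
    values = np.log2(rq.rq) if log_scale else rq.rq
    records = []
    for earlier, later in combinations(scheme.periods, 2):
        a = values[list(earlier.samples)]
        b = values[list(later.samples)]
        for mirna in values.index:
            x = a.loc[mirna].dropna().to_numpy(dtype=float)
            y = b.loc[mirna].dropna().to_numpy(dtype=float)
            testable = len(x) >= 2 and len(y) >= 2
            mean_earlier = float(np.mean(x)) if len(x) else np.nan
            mean_later = float(np.mean(y)) if len(y) else np.nan
            if testable:
                t, p = _pooled_ttest(x, y, equal_var)
                direction = int(np.sign(mean_later - mean_earlier))
            else:
                t, p, direction = np.nan, np.nan, 0
            records.append(
                {
                    "mirna_id": mirna,
                    "period_earlier": earlier.name,
                    "period_later": later.name,
                    "n_earlier": len(x),
                    "n_later": len(y),
                    "mean_earlier": mean_earlier,
                    "mean_later": mean_later,
                    "direction": direction,
                    "t": t,
                    "p_value": p,
                    "testable": testable,
                }
            )
    return pd.DataFrame.from_records(records)


def classify_groups(tests: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Assign each tested microRNA to Group I, II, III or AMBIGUOUS.

    A transition contributes to Group I (II) when its two-tailed p is
    strictly below ``alpha`` and the later-period mean is higher (lower).
    Untestable comparisons never count as significant. Ties in means
    (direction 0) contribute to neither direction.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rows = []
    for mirna, sub in tests.groupby("mirna_id", sort=False):
        significant = sub[(sub["p_value"] < alpha) & sub["testable"]]
        up = (significant["direction"] > 0).any()
        down = (significant["direction"] < 0).any()
        if up and down:
            group = "AMBIGUOUS"
        elif up:
            group = "I"
        elif down:
            group = "II"
        else:
            group = "III"
        rows.append(
            {
                "mirna_id": mirna,
                "group": group,
                "n_significant_up": int((significant["direction"] > 0).sum()),
                "n_significant_down": int((significant["direction"] < 0).sum()),
                "min_p": float(sub["p_value"].min()),
            }
        )
    return pd.DataFrame.from_records(
        rows, columns=["mirna_id", "group", "n_significant_up", "n_significant_down", "min_p"]
    )
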