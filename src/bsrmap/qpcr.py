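"""Relative expression by the 2^-ddCt method with a two-group t-test.

Per replicate, dCt = Ct(target) - Ct(reference); ddCt subtracts the mean
dCt of the calibrator group within the same tissue; relative expression is
2^-ddCt. A group is summarised as 2^-(mean ddCt) — so the calibrator's
summary fold is exactly 1 by construction — with the sd taken over the
replicate-level folds. Replicate-level folds (not group means) feed a
two-sided t-test against the calibrator, preserving biological-replicate
variance. Welch's unequal-variance form is the default; Student's pooled
form is available via a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import QpcrMeasurement

__all__ = ["RelativeExpression", "delta_delta_ct", "group_ttest"]


@dataclass
class RelativeExpression:
    group: str
    tissue: str
    n: int
    mean_fold_change: float
    sd: float
    p_value: float | None  # None for the calibrator group itself
    significant: bool


def group_ttest(
    folds_group1: Sequence[float],
    folds_group2: Sequence[float],
    alpha: float = 0.05,
    welch: bool = True,
) -> tuple[float, bool]:
    """Two-sided two-sample t-test on replicate fold changes.

    Degenerate zero-variance inputs are guarded: equal-mean groups give
    p = 1.0, separated zero-variance groups give p = 0.0.
    """
    a = np.asarray(folds_group1, dtype=float)
    b = np.asarray(folds_group2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)
    return p, p < alpha


def delta_delta_ct(
    measurements: Sequence[QpcrMeasurement],
    calibrator: str = "wildtype",
    alpha: float = 0.05,
    welch: bool = True,
) -> list[RelativeExpression]:
    """Relative expression per group x tissue, calibrated within tissue.

    Tissues lacking the calibrator group are skipped with a warning. The
    calibrator's summary fold change is 1 by construction (each group is
    summarised as 2^-(mean ddCt), and the calibrator is calibrated against
    its own mean dCt). The p-value compares each group's replicate folds
    with the calibrator's; it is None when either side has fewer than two
    replicates.
    """
    import logging

    logger = logging.getLogger("bsrmap")
    df = pd.DataFrame(
        {
            "group": [m.group for m in measurements],
            "tissue": [m.tissue for m in measurements],
            "dct": [m.ct_target - m.ct_reference for m in measurements],
        }
    )
    if df.empty:
        raise ValueError("no measurements")
    out: list[RelativeExpression] = []
    for tissue, sub in df.groupby("tissue", sort=True):
        cal = sub[sub["group"] == calibrator]
        if cal.empty:
            logger.warning("tissue %s has no calibrator (%s) replicates; skipped",
                           tissue, calibrator)
            continue
        cal_mean_dct = cal["dct"].mean()
        folds = {}
        mean_fold = {}
        for group, g in sub.groupby("group", sort=True):
            ddct = np.asarray(g["dct"]) - cal_mean_dct
            folds[group] = 2.0**-ddct
            mean_fold[group] = float(2.0 ** -ddct.mean())
        for group, f in folds.items():
            if group == calibrator:
                p, sig = None, False
            elif f.size >= 2 and folds[calibrator].size >= 2:
                p, sig = group_ttest(f, folds[calibrator], alpha=alpha, welch=welch)
            else:
                p, sig = None, False
            out.append(
                RelativeExpression(
                    group=group,
                    tissue=tissue,
                    n=int(f.size),
                    mean_fold_change=mean_fold[group],
                    sd=float(f.std(ddof=1)) if f.size > 1 else 0.0,
                    p_value=p,
                    significant=sig,
                )
            )
    return out
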