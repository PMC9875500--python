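"""Post-critical expression reversal ("flip-flop") of DNB-neighboring genes.

A gene reverses across the critical stage t* when its per-stage mean
expression trends in opposite directions before and after the transition.
Each window includes the critical stage itself (before: stages 1..t*,
after: t*..T), so both windows have at least two points whenever t* is
interior.  The reversal score is -(slope_before * slope_after): positive
exactly when the two least-squares slopes have opposite signs.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from scle.expression_io import StageSeries

logger = logging.getLogger(__name__)


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    # least-squares slope of y on x
    xc = x - x.mean()
    return float((xc @ (y - y.mean())) / (xc @ xc))


def reversal_scan(
    series: StageSeries,
    genes,
    critical_stage: str,
    epsilon: float = 1e-6,
) -> pd.DataFrame:
    """Score each gene for a trend reversal around ``critical_stage``.

    Returns one row per gene with the per-stage means, the two window
    slopes, ``reversal_score`` and the boolean ``reversed`` flag
    (score > 0 and both |slopes| > epsilon), sorted by score descending.
    When the critical stage is first or last in the series no reversal can
    be defined; all genes are flagged False with a logged explanation.
    """
    if critical_stage not in series.stage_order:
        raise ValueError(f"unknown critical stage {critical_stage!r}")
    t_star = series.stage_order.index(critical_stage)
    T = series.n_stages
    interior = 1 <= t_star <= T - 2
    if not interior:
        logger.info(
            "critical stage %r is at the series boundary; "
            "reversal undefined, all genes flagged False",
            critical_stage,
        )
    gi = series.matrix.gene_index()
    genes = sorted(set(genes))
    missing = [g for g in genes if g not in gi]
    if missing:
        raise KeyError(f"gene {missing[0]!r} is not in the expression matrix")

    idx = [gi[g] for g in genes]
    means = np.column_stack(
        [series.stage_values(s)[idx, :].mean(axis=1) for s in series.stage_order]
    )
    t = np.arange(1, T + 1, dtype=float)
    rows = []
    for k, gene in enumerate(genes):
        if interior:
            before = _slope(t[: t_star + 1], means[k, : t_star + 1])
            after = _slope(t[t_star:], means[k, t_star:])
            score = -(before * after)
            rev = score > 0 and abs(before) > epsilon and abs(after) > epsilon
        else:
            before = after = score = math.nan
            rev = False
        row = {"gene": gene}
        row.update(
            {f"mean_{s}": means[k, j] for j, s in enumerate(series.stage_order)}
        )
        row.update(
            {
                "slope_before": before,
                "slope_after": after,
                "reversal_score": score,
                "reversed": rev,
            }
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["reversal_score", "gene"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
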