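"""Exact and elementary statistics shared across the pipeline.

Implements the two-sided Fisher exact test for 2x2 contingency tables by
direct hypergeometric enumeration (probability-mass two-siding, the R
convention), the Welch unequal-variance t-test used by every group
comparison in the package, and relative qPCR quantification by the
delta-delta-Ct method with multiple reference genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "fisher_exact_2x2",
    "welch_t",
    "delta_delta_ct",
    "DeltaDeltaCtResult",
]

log = logging.getLogger(__name__)

#: relative tolerance guarding float ties in the probability-mass rule
_FISHER_TIE_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of a 2x2 table; rows = genotype, columns = trait.

    Layout::

        [[a, b],
         [c, d]]
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise ValueError(f"counts must be non-negative integers, got {counts}")
        if sum(counts) < 1:
            raise ValueError("table total must be >= 1")

    def transpose(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.a, self.c, self.b, self.d)


def fisher_exact_2x2(table: ContingencyTable2x2 | tuple) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Conditions on both margins and enumerates the hypergeometric
    distribution of the top-left cell; the two-sided p-value sums the
    probabilities of every table at most as probable as the observed one
    (with a ``1 + 1e-7`` relative tolerance absorbing floating-point ties).
    A table with an empty row or column carries no information and returns
    p = 1.

    Parameters
    ----------
    table : ContingencyTable2x2 or 4-tuple
        Counts ``(a, b, c, d)`` read row-wise.

    Returns
    -------
    float
        Two-sided p-value in (0, 1].
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        return 1.0

    k_min = max(0, row1 + col1 - n)
    k_max = min(row1, col1)
    support = np.arange(k_min, k_max + 1)
    pmf = sps.hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - k_min]
    p = float(pmf[pmf <= p_obs * (1.0 + _FISHER_TIE_TOL)].sum())
    return min(p, 1.0)


def welch_t(x, y):
    """Welch two-sample t-test (unequal variances), two-sided.

    Returns ``(mean_x, mean_y, t, p)`` where ``t`` is signed as
    ``mean_x - mean_y``.  Degenerate inputs with zero variance in both
    groups report t = 0, p = 1 when the means are equal, and an infinite
    t with p = 0 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 observations")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if mx == my:
            return mx, my, 0.0, 1.0
        return mx, my, np.sign(mx - my) * np.inf, 0.0
    res = sps.ttest_ind(x, y, equal_var=False)
    return mx, my, float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# delta-delta-Ct qPCR quantification
# ---------------------------------------------------------------------------

@dataclass
class DeltaDeltaCtResult:
    """Per-sample fold changes and the group-level summary."""

    per_sample: pd.DataFrame           # sample, group, delta_ct, ddct, fold_change
    group_fold_change: dict[str, float]  # geometric-mean fold change per group
    t_stat: float
    p_value: float
    n_dropped: int


def delta_delta_ct(records: pd.DataFrame, target: str, refs: list[str],
                   calibrator_group: str = "WT") -> DeltaDeltaCtResult:
    """Relative expression of ``target`` by the delta-delta-Ct method.

    ``records`` is tidy with columns ``sample``, ``group``, ``gene``, ``ct``
    (one row per technical replicate).  Replicate Cts are averaged per
    sample and gene; dCt = Ct_target - mean(Ct of reference genes);
    ddCt = dCt - mean(dCt of the calibrator group); fold change =
    2**(-ddCt).  Samples missing the target or any reference gene are
    dropped with a logged count.  Group fold changes are geometric means
    (2**(-mean ddCt)), so the calibrator group's summary fold change is 1
    by construction; the group comparison is a Welch two-sided t-test on
    the per-sample dCt values.
    """
    needed = {"sample", "group", "gene", "ct"}
    if not needed.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(needed)}")
    ct = (records[records["ct"].notna()]
          .groupby(["sample", "group", "gene"])["ct"].mean().unstack("gene"))

    wanted = [target] + list(refs)
    missing_cols = [g for g in wanted if g not in ct.columns]
    if missing_cols:
        raise ValueError(f"no Ct values at all for gene(s) {missing_cols}")
    complete = ct[wanted].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("delta_delta_ct: dropped %d sample(s) missing target/reference Cts",
                 n_dropped)
    ct = ct[complete]

    delta_ct = ct[target] - ct[list(refs)].mean(axis=1)
    groups = delta_ct.index.get_level_values("group")
    if calibrator_group not in set(groups):
        raise ValueError(f"no samples in calibrator group {calibrator_group!r}")
    ddct = delta_ct - delta_ct[groups == calibrator_group].mean()
    fold = 2.0 ** (-ddct)

    per_sample = pd.DataFrame({
        "sample": delta_ct.index.get_level_values("sample"),
        "group": groups,
        "delta_ct": delta_ct.values,
        "ddct": ddct.values,
        "fold_change": fold.values,
    })
    group_fc = {
        g: float(2.0 ** (-ddct[groups == g].mean())) for g in sorted(set(groups))
    }

    other = [g for g in sorted(set(groups)) if g != calibrator_group]
    if other and (groups == other[0]).sum() >= 2 and (groups == calibrator_group).sum() >= 2:
        _, _, t, p = welch_t(delta_ct[groups == other[0]],
                             delta_ct[groups == calibrator_group])
    else:
        t, p = np.nan, np.nan
    return DeltaDeltaCtResult(per_sample=per_sample, group_fold_change=group_fc,
                              t_stat=t, p_value=p, n_dropped=n_dropped)
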