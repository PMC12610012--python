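"""Per-protein differential statistics and the two-cohort concordance screen.

The screen mirrors a discovery/validation design for tandem-mass-tag
proteomics: Welch t-tests with Storey q-value control in the discovery
cohort, then a four-stage cascade that keeps proteins which (1) pass the
discovery q-value cut, (2) are also quantified in the validation cohort,
(3) shift in the same direction in both cohorts, and (4) rank within the
top decile of their own side (up- or downregulated) in both cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import UnivariateSpline

from .io import ExpressionMatrix
from .stats import welch_t

__all__ = [
    "CohortStats",
    "ScreenConfig",
    "ScreenResult",
    "compute_group_stats",
    "storey_pi0",
    "storey_qvalues",
    "concordance_screen",
    "welch_group_compare",
]

log = logging.getLogger(__name__)


@dataclass
class CohortStats:
    """Per-feature differential statistics for one cohort.

    ``table`` is indexed by feature id with columns ``log2fc`` (MUT mean
    minus WT mean on the log2 scale), ``t``, ``p``, ``q``, ``direction``
    (sign of log2fc), ``up_percentile`` and ``down_percentile`` (rank
    fraction within the matching side, rank 1 = strongest, NaN on the
    other side), and ``degenerate`` (zero variance in both groups).
    """

    table: pd.DataFrame
    n_dropped_missing: int = 0

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class ScreenConfig:
    """Cutoffs of the concordance screen."""

    q_max: float = 0.1          # discovery q-value cut ("q below 0.1")
    decile: float = 0.10        # within-side rank fraction kept in both cohorts
    per_side: bool = True       # rank among up / among down separately
    rank_by: str = "log2fc"     # or "t"

    def __post_init__(self) -> None:
        if not 0 < self.q_max < 1:
            raise ValueError("q_max must be in (0,1)")
        if not 0 < self.decile <= 0.5:
            raise ValueError("decile must be in (0, 0.5]")
        if self.rank_by not in ("log2fc", "t"):
            raise ValueError("rank_by must be 'log2fc' or 't'")


def compute_group_stats(matrix: ExpressionMatrix, rank_by: str = "log2fc") -> CohortStats:
    """Welch differential statistics (MUT vs WT) for every feature.

    Features with any missing value in either group are dropped with a
    logged count.  Constant features (zero variance in both groups, equal
    means) are degenerate: they report t = 0, p = 1 and are flagged.
    Two-sided p-values use the Welch-Satterthwaite degrees of freedom.
    Storey q-values are attached, and within-side rank percentiles are
    computed for the concordance screen (ties broken by feature id).
    """
    wt = matrix.samples_in("WT")
    mut = matrix.samples_in("MUT")
    if len(wt) < 2 or len(mut) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got WT={len(wt)} MUT={len(mut)}"
        )
    vals = matrix.values
    complete = vals[wt + mut].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("compute_group_stats: dropped %d feature(s) with missing values",
                 n_dropped)
    vals = vals[complete]

    a = vals[mut].to_numpy(float)   # MUT first: log2fc = MUT - WT
    b = vals[wt].to_numpy(float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)

    res = sps.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(res.statistic, float)
    p = np.asarray(res.pvalue, float)

    degen = (va == 0) & (vb == 0)
    if degen.any():
        log.info("compute_group_stats: %d degenerate constant feature(s)",
                 int(degen.sum()))
        eq = degen & (log2fc == 0)
        t[eq], p[eq] = 0.0, 1.0
        ne = degen & (log2fc != 0)
        t[ne], p[ne] = np.sign(log2fc[ne]) * np.inf, 0.0

    table = pd.DataFrame({
        "log2fc": log2fc, "t": t, "p": p,
        "direction": np.sign(log2fc).astype(int),
        "degenerate": degen,
    }, index=vals.index)
    table["q"] = storey_qvalues(table["p"].to_numpy())
    _attach_side_percentiles(table, rank_by=rank_by)
    return CohortStats(table=table, n_dropped_missing=n_dropped)


def _attach_side_percentiles(table: pd.DataFrame, rank_by: str = "log2fc") -> None:
    """Within-side rank percentiles: rank/n_side, rank 1 = strongest effect.

    The up side ranks features with log2fc > 0 by descending magnitude of
    the chosen metric, the down side those with log2fc < 0 by ascending
    signed metric; zero-fold-change features belong to neither side.
    Ties are broken lexicographically by feature id for determinism.
    """
    metric = table[rank_by].to_numpy(float)
    table["up_percentile"] = np.nan
    table["down_percentile"] = np.nan
    for side, col in ((1, "up_percentile"), (-1, "down_percentile")):
        mask = table["direction"] == side
        n_side = int(mask.sum())
        if n_side == 0:
            continue
        sub = table.loc[mask]
        order = sorted(range(n_side),
                       key=lambda i: (-side * metric[mask.to_numpy()][i], sub.index[i]))
        ranks = np.empty(n_side)
        ranks[order] = np.arange(1, n_side + 1)
        table.loc[mask, col] = ranks / n_side


def storey_pi0(p_values, lambdas=None) -> float:
    """Smoothed Storey estimate of the true-null fraction pi0.

    ``pi0(lambda) = #{p > lambda} / (n (1 - lambda))`` on a lambda grid
    (default 0.05..0.95 step 0.05), smoothed with a cubic smoothing
    spline and read off at the largest lambda, clamped to (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    lambdas = np.asarray(lambdas, float)
    pi0_lam = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    spline = UnivariateSpline(lambdas, pi0_lam, k=3)
    return min(max(float(spline(lambdas[-1])), 1e-8), 1.0)


def storey_qvalues(p_values, lambdas=None, pi0: float | None = None) -> np.ndarray:
    """Storey q-values with smoothed pi0 estimation.

    pi0 (the fraction of true nulls) is estimated on the grid
    lambda = 0.05, 0.10, ..., 0.95 as ``#{p > lambda} / (n (1 - lambda))``,
    smoothed with a cubic smoothing spline, evaluated at the largest
    lambda and clamped to (0, 1].  q-values are the step-down minimum of
    ``pi0 * n * p_(j) / j`` over j >= i on the sorted p-values, hence
    monotone non-decreasing in p; with ``pi0=1`` this is exactly the
    Benjamini-Hochberg adjustment.  Fewer than 10 p-values fall back to
    pi0 = 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-d")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if n == 0:
        return p.copy()

    if pi0 is None:
        pi0 = 1.0 if n < 10 else storey_pi0(p, lambdas)
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must be in (0, 1]")

    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    ranks = np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate((pi0 * n * p_sorted / ranks)[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


@dataclass
class ScreenResult:
    """Surviving features plus a per-stage audit of the cascade."""

    validated: list[str]
    stage_counts: dict[str, int] = field(default_factory=dict)
    audit: pd.DataFrame | None = None


def concordance_screen(discovery: CohortStats, validation: CohortStats,
                       cfg: ScreenConfig = ScreenConfig()) -> ScreenResult:
    """Four-stage discovery/validation concordance cascade.

    Stage 1 keeps discovery features with q < ``q_max``; stage 2 those
    also quantified in the validation cohort; stage 3 those whose fold
    change has the same (nonzero) sign in both cohorts; stage 4 those
    within the top ``decile`` rank fraction of their own side in BOTH
    cohorts.  Returns the survivors, per-stage counts, and an audit table
    of per-feature booleans for every stage.
    """
    disc = discovery.table
    val = validation.table

    s1 = disc["q"] < cfg.q_max
    s2 = s1 & disc.index.isin(val.index)
    shared = disc.index[s2]
    same_sign = pd.Series(False, index=disc.index)
    if len(shared):
        d_dir = disc.loc[shared, "direction"]
        v_dir = val.loc[shared, "direction"]
        same_sign.loc[shared] = (d_dir == v_dir) & (d_dir != 0)
    s3 = s2 & same_sign

    if cfg.per_side:
        d_pct = disc["up_percentile"].where(disc["direction"] == 1,
                                            disc["down_percentile"])
        v_pct = val["up_percentile"].where(val["direction"] == 1,
                                           val["down_percentile"])
    else:
        d_pct = _global_percentile(disc, cfg.rank_by)
        v_pct = _global_percentile(val, cfg.rank_by)
    s4 = s3.copy()
    surv3 = disc.index[s3]
    s4.loc[surv3] = ((d_pct.loc[surv3] <= cfg.decile)
                     & (v_pct.reindex(surv3) <= cfg.decile)).fillna(False)

    counts = {
        "discovery_q": int(s1.sum()),
        "in_validation": int(s2.sum()),
        "same_direction": int(s3.sum()),
        "top_decile_both": int(s4.sum()),
    }
    if counts["discovery_q"] == 0:
        log.info("concordance_screen: no feature passed the discovery q cut")
    audit = pd.DataFrame({
        "stage1_q": s1, "stage2_in_validation": s2,
        "stage3_same_direction": s3, "stage4_top_decile": s4,
    }, index=disc.index)
    return ScreenResult(validated=sorted(disc.index[s4]),
                        stage_counts=counts, audit=audit)


def _global_percentile(table: pd.DataFrame, rank_by: str) -> pd.Series:
    """Rank fraction by |metric| over all features (the non-per-side variant)."""
    mag = table[rank_by].abs()
    order = sorted(table.index, key=lambda f: (-mag[f], f))
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order, dtype=float)
    return ranks.reindex(table.index) / len(table)


def welch_group_compare(values, groups):
    """Welch comparison of a per-sample score between two label groups.

    ``groups`` are arbitrary labels with exactly two levels; the first
    level in sorted order is group a.  Returns ``(mean_a, mean_b, t, p)``
    with t signed as mean_a - mean_b.  Used for precomputed score tables
    (e.g. immune-deconvolution fractions) and density comparisons.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, got {levels}")
    return welch_t(values[groups == levels[0]], values[groups == levels[1]])
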