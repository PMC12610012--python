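"""Preranked gene-set enrichment analysis and the three-dataset consistency filter.

The enrichment score is the weighted Kolmogorov-Smirnov running-sum
statistic of preranked GSEA: walking down the ranked list, hitting a set
member adds its weight ``|metric|^p / sum(|metric|^p over members)`` and
missing subtracts ``1 / (N - n_hits)``; the score is the signed extreme
deviation of the running sum.  Significance and normalization use
gene-label permutations: NES divides the observed score by the mean
magnitude of same-sign permutation scores (the GSEA convention), and the
permutation p-value is ``(1 + #more extreme same-sign) / (1 + #same-sign)``.

The consistency filter keeps pathways whose NES has the same sign in all
three datasets (discovery proteome, validation proteome, validation
transcriptome) and lies within the top ``pct`` (positive) or bottom
``pct`` (negative) of each dataset's NES distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneSetCollection
from .screen import CohortStats

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "ConsistencyConfig",
    "NoOverlapError",
    "filter_gene_sets",
    "make_ranked_list",
    "enrichment_score",
    "gsea_permutation",
    "run_gsea",
    "consistency_filter",
]

log = logging.getLogger(__name__)


class NoOverlapError(ValueError):
    """The gene set shares no member with the ranked list."""


@dataclass(frozen=True)
class ConsistencyConfig:
    pct: float = 0.15       # NES tail fraction required in every dataset
    n_perm: int = 1000
    weight_p: float = 1.0   # exponent on |metric| in the hit weights
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pct <= 0.5:
            raise ValueError("pct must be in (0, 0.5]")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")


@dataclass
class RankedList:
    """Feature ids ordered by descending metric, ties broken by id."""

    ids: np.ndarray      # str array, descending metric order
    metric: np.ndarray   # float array aligned with ids

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.metric):
            raise ValueError("ids and metric must align")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in ranked list")

    def __len__(self) -> int:
        return len(self.ids)


def make_ranked_list(stats: CohortStats, metric: str = "log2fc") -> RankedList:
    """Rank features by descending differential metric (default log2fc)."""
    table = stats.table
    if len(table) == 0:
        raise ValueError("empty cohort statistics")
    vals = table[metric]
    order = sorted(table.index, key=lambda f: (-vals[f], f))
    return RankedList(ids=np.asarray(order, dtype=object),
                      metric=vals.loc[order].to_numpy(float))


def filter_gene_sets(collection: GeneSetCollection, proteins) -> GeneSetCollection:
    """Keep gene sets containing at least one protein of interest."""
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    proteins = set(proteins)
    keep = [name for name in collection.names()
            if proteins.intersection(collection.members(name))]
    return collection.subset(keep)


def enrichment_score(ranked: RankedList, gene_set, weight_p: float = 1.0):
    """Weighted KS enrichment score and the full running sum.

    Returns ``(es, running_sum)`` where ``running_sum[i]`` is the deviation
    after processing position i, and ``es`` is the deviation of maximal
    magnitude (signed; ties between the positive and negative extremes
    resolve to the positive one).
    """
    members = set(gene_set)
    hit = np.fromiter((fid in members for fid in ranked.ids), dtype=bool,
                      count=len(ranked))
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise NoOverlapError("gene set has no member in the ranked list")
    if n_hits == len(ranked):
        raise ValueError("gene set covers the whole ranked list")

    w = np.abs(ranked.metric) ** weight_p
    step = np.where(hit, 0.0, -1.0 / (len(ranked) - n_hits))
    denom = w[hit].sum()
    if denom == 0:  # all-zero metric over hits: fall back to unweighted hits
        step[hit] = 1.0 / n_hits
    else:
        step[hit] = w[hit] / denom
    running = np.cumsum(step)
    es = _signed_extreme(running.max(), running.min())
    return float(es), running


def _signed_extreme(pos: float, neg: float) -> float:
    return pos if pos >= -neg else neg


def _es_from_positions(pos: np.ndarray, w: np.ndarray, n: int) -> float:
    """Enrichment score from sorted hit positions only (O(k) per call).

    ``pos`` are the 0-based ranks of the hits (ascending), ``w`` their
    weights aligned with ``pos``.  The running sum attains its positive
    extremes immediately after a hit and its negative extremes immediately
    before one, which is all that is needed for the signed extreme.
    """
    k = pos.size
    denom = w.sum()
    if denom == 0:
        cum_hit = np.arange(1, k + 1) / k
    else:
        cum_hit = np.cumsum(w) / denom
    miss_rate = 1.0 / (n - k)
    misses_before = pos - np.arange(k)          # misses strictly before hit i
    after = cum_hit - misses_before * miss_rate
    before = np.concatenate(([0.0], cum_hit[:-1])) - misses_before * miss_rate
    return _signed_extreme(after.max(), min(before.min(), 0.0))


@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    p_perm: float
    n_hits: int
    dataset: str = ""
    flagged: bool = False  # NES undefined (no same-sign permutation scores)


def gsea_permutation(ranked: RankedList, gene_set, cfg: ConsistencyConfig,
                     rng: np.random.Generator | None = None,
                     name: str = "") -> EnrichmentResult:
    """Permutation-normalized enrichment of one gene set.

    Gene-label permutation: the observed hit positions are replaced by
    ``n_hits`` ranks drawn uniformly without replacement, ``n_perm`` times.
    NES = es / mean(|permutation es| of the same sign); p_perm counts
    same-sign permutation scores at least as extreme, with the +1
    continuity correction.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    es, _ = enrichment_score(ranked, gene_set, cfg.weight_p)
    members = set(gene_set)
    hit_mask = np.fromiter((fid in members for fid in ranked.ids), dtype=bool,
                           count=len(ranked))
    k = int(hit_mask.sum())
    n = len(ranked)
    w_all = np.abs(ranked.metric) ** cfg.weight_p

    perm_es = np.empty(cfg.n_perm)
    for i in range(cfg.n_perm):
        pos = np.sort(_sample_positions(rng, n, k))
        perm_es[i] = _es_from_positions(pos, w_all[pos], n)

    same = perm_es * np.sign(es) > 0 if es != 0 else np.ones(cfg.n_perm, bool)
    n_same = int(same.sum())
    if n_same == 0:
        log.warning("gsea_permutation: no same-sign permutation score for %s", name)
        return EnrichmentResult(name=name, es=es, nes=np.nan, p_perm=1.0,
                                n_hits=k, flagged=True)
    nes = es / np.abs(perm_es[same]).mean()
    p = (1 + int((np.abs(perm_es[same]) >= abs(es)).sum())) / (1 + n_same)
    return EnrichmentResult(name=name, es=es, nes=float(nes), p_perm=float(p),
                            n_hits=k)


def _sample_positions(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """k distinct ranks uniform in [0, n); collision-resample (k << n)."""
    pos = rng.integers(0, n, size=k)
    while True:
        uniq = np.unique(pos)
        if uniq.size == k:
            return pos
        extra = rng.integers(0, n, size=k - uniq.size)
        pos = np.concatenate([uniq, extra])


def run_gsea(ranked: RankedList, collection: GeneSetCollection,
             cfg: ConsistencyConfig, dataset: str = "") -> pd.DataFrame:
    """Score every set of a collection against one ranked list.

    Sets with no overlap are reported with NaN scores and flagged.  The
    permutation stream is seeded per set from ``cfg.seed`` and the set
    name, so results do not depend on collection order.
    """
    rows = []
    for set_name in collection.names():
        members = collection.members(set_name)
        seed = (cfg.seed * 100003 + _stable_hash(set_name)) % (2 ** 31)
        rng = np.random.default_rng(seed)
        try:
            res = gsea_permutation(ranked, members, cfg, rng=rng, name=set_name)
        except NoOverlapError:
            res = EnrichmentResult(name=set_name, es=np.nan, nes=np.nan,
                                   p_perm=np.nan, n_hits=0, flagged=True)
        rows.append({"name": res.name, "es": res.es, "nes": res.nes,
                     "p_perm": res.p_perm, "n_hits": res.n_hits,
                     "dataset": dataset, "flagged": res.flagged})
    return pd.DataFrame(rows).set_index("name")


def _stable_hash(text: str) -> int:
    h = 0
    for ch in text:
        h = (h * 131 + ord(ch)) % (2 ** 31 - 1)
    return h


def consistency_filter(tables: dict[str, pd.DataFrame], pct: float = 0.15):
    """Pathways consistently extreme across all datasets.

    A pathway is kept when (a) its NES carries the same nonzero sign in
    every table and (b) in every table its NES lies within the top ``pct``
    fraction (positive sign) or bottom ``pct`` fraction (negative sign)
    of that table's NES distribution.  The tail test is boundary
    inclusive: a pathway is in the tail when the fraction of scored
    pathways STRICTLY more extreme than it is below ``pct`` (so ties at
    the cutoff are kept, and a single-pathway table trivially passes).
    Pathways missing or flagged in any table are excluded with a logged
    count.

    Returns ``(names, audit)`` with the surviving pathway names (sorted)
    and a per-pathway boolean audit frame.
    """
    if len(tables) < 2:
        raise ValueError("need at least two result tables")
    names_sets = []
    for tag, tbl in tables.items():
        ok = tbl.index[tbl["nes"].notna()]
        names_sets.append(set(ok))
    common = set.intersection(*names_sets)
    all_names = set.union(*(set(t.index) for t in tables.values()))
    n_excluded = len(all_names) - len(common)
    if n_excluded:
        log.info("consistency_filter: excluded %d pathway(s) missing or "
                 "unscored in some dataset", n_excluded)

    audit = pd.DataFrame(index=sorted(common))
    keep = pd.Series(True, index=audit.index)
    signs = pd.DataFrame({tag: np.sign(tbl["nes"].reindex(audit.index))
                          for tag, tbl in tables.items()})
    sign_ok = signs.apply(lambda row: row.nunique() == 1 and row.iloc[0] != 0,
                          axis=1)
    audit["same_sign"] = sign_ok
    keep &= sign_ok

    for tag, tbl in tables.items():
        nes_all = tbl["nes"].dropna()
        n = len(nes_all)
        nes = tbl["nes"].reindex(audit.index)
        # fraction of scored pathways strictly more extreme, same tail
        frac_top = nes.map(lambda x: (nes_all > x).sum() / n)
        frac_bot = nes.map(lambda x: (nes_all < x).sum() / n)
        in_tail = np.where(nes > 0, frac_top < pct, frac_bot < pct)
        col = pd.Series(in_tail, index=audit.index)
        audit[f"tail_{tag}"] = col
        keep &= col

    audit["kept"] = keep
    return sorted(audit.index[keep]), audit
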