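"""Enrichment score vs a brute-force running-sum oracle; permutation NES;
three-dataset consistency filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wntomics.gsea import (ConsistencyConfig, NoOverlapError, RankedList,
                           _es_from_positions, consistency_filter,
                           enrichment_score, filter_gene_sets,
                           gsea_permutation, make_ranked_list, run_gsea)
from wntomics.io import GeneSetCollection
from wntomics.screen import compute_group_stats


def brute_force_es(ids, metric, members, p):
    """Independent step-by-step running sum, the textbook loop."""
    members = set(members)
    hits = [i for i, f in enumerate(ids) if f in members]
    n, k = len(ids), len(hits)
    denom = sum(abs(metric[i]) ** p for i in hits)
    running, cur = [], 0.0
    for i, f in enumerate(ids):
        if f in members:
            cur += (abs(metric[i]) ** p) / denom if denom > 0 else 1.0 / k
        else:
            cur -= 1.0 / (n - k)
        running.append(cur)
    pos, neg = max(running), min(running)
    return (pos if pos >= -neg else neg), running


def ranked_from(metric, ids=None):
    metric = np.asarray(metric, float)
    if ids is None:
        ids = [f"g{i}" for i in range(len(metric))]
    return RankedList(ids=np.asarray(ids, dtype=object), metric=metric)


class TestFilterGeneSets:
    def make(self):
        return GeneSetCollection({
            "A": ("", ["g1", "g2"]), "B": ("", ["g3"]), "C": ("", ["g1", "g4"]),
        })

    def test_disjoint_proteins_empty(self):
        assert len(filter_gene_sets(self.make(), {"zz"})) == 0

    def test_universe_keeps_all(self):
        coll = self.make()
        assert filter_gene_sets(coll, {"g1", "g2", "g3", "g4"}).names() == coll.names()

    def test_matches_hand_membership_check(self, rng):
        universe = [f"g{i}" for i in range(60)]
        sets = {f"S{i}": ("", list(rng.choice(universe, 8, replace=False)))
                for i in range(50)}
        coll = GeneSetCollection(sets)
        proteins = set(rng.choice(universe, 10, replace=False))
        kept = filter_gene_sets(coll, proteins)
        expected = [n for n, (_, m) in sets.items() if proteins & set(m)]
        assert kept.names() == expected


class TestRankedList:
    def test_descending_and_tie_rule(self):
        tbl = pd.DataFrame({"log2fc": [0.5, 2.0, 0.5, -1.0]},
                           index=["B", "top", "A", "bottom"])
        from wntomics.screen import CohortStats
        ranked = make_ranked_list(CohortStats(table=tbl))
        assert list(ranked.ids) == ["top", "A", "B", "bottom"]

    def test_generated_cohort_head_is_max(self, small_cohort):
        discovery, _, _, _ = small_cohort
        stats = compute_group_stats(discovery)
        ranked = make_ranked_list(stats)
        assert ranked.metric[0] == stats.table["log2fc"].max()


class TestEnrichmentScore:
    def test_top1_unweighted_closed_form(self):
        ranked = ranked_from(np.linspace(10, 1, 10))
        es, running = enrichment_score(ranked, ["g0"], weight_p=0.0)
        expected, _ = brute_force_es(ranked.ids, ranked.metric, ["g0"], 0.0)
        assert es == pytest.approx(expected)
        assert es == pytest.approx(1.0)     # hit at rank 1 tops the running sum
        assert running[0] == pytest.approx(1.0)

    def test_p_zero_reduces_to_classic_ks(self, rng):
        metric = rng.normal(size=40)
        order = np.argsort(-metric)
        ranked = ranked_from(metric[order])
        members = list(rng.choice(ranked.ids, 8, replace=False))
        es, _ = enrichment_score(ranked, members, weight_p=0.0)
        # classic KS: equal hit increments regardless of the metric values
        es_flat, _ = enrichment_score(ranked_from(np.ones(40), ranked.ids),
                                      members, weight_p=1.0)
        assert es == pytest.approx(es_flat)

    def test_no_overlap_distinct_error(self):
        with pytest.raises(NoOverlapError):
            enrichment_score(ranked_from([3, 2, 1]), ["absent"])

    @given(st.integers(5, 100), st.integers(1, 20), st.integers(0, 10 ** 6))
    @settings(deadline=None, derandomize=True, max_examples=80)
    def test_matches_brute_force_oracle(self, n, k, seed):
        k = min(k, n - 1)
        rng = np.random.default_rng(seed)
        metric = np.sort(rng.normal(size=n))[::-1]
        ranked = ranked_from(metric)
        members = list(rng.choice(ranked.ids, k, replace=False))
        es, running = enrichment_score(ranked, members, weight_p=1.0)
        es_bf, running_bf = brute_force_es(ranked.ids, ranked.metric,
                                           members, 1.0)
        assert es == pytest.approx(es_bf, abs=1e-12)
        assert np.allclose(running, running_bf, atol=1e-12)
        assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12
        # the O(k) hit-position shortcut used inside permutations agrees too
        hit_pos = np.sort([list(ranked.ids).index(m) for m in members])
        w = np.abs(ranked.metric[hit_pos])
        assert _es_from_positions(hit_pos, w, n) == pytest.approx(es, abs=1e-12)

    def test_reversal_negates_es(self, rng):
        metric = np.sort(rng.normal(size=30))[::-1]
        ranked = ranked_from(metric)
        members = list(rng.choice(ranked.ids, 6, replace=False))
        es, _ = enrichment_score(ranked, members)
        rev = RankedList(ids=ranked.ids[::-1].copy(),
                         metric=ranked.metric[::-1].copy())
        es_rev, _ = enrichment_score(rev, members)
        assert es_rev == pytest.approx(-es, abs=1e-12)


class TestPermutation:
    def test_random_set_nes_centered_near_one(self):
        """|NES| of null sets averages ~1 under the same-sign normalization."""
        ranked = ranked_from(np.sort(np.random.default_rng(5).normal(size=200))[::-1])
        cfg = ConsistencyConfig(n_perm=100, seed=0)
        vals = []
        for seed in range(200):
            rng = np.random.default_rng(1000 + seed)
            members = list(rng.choice(ranked.ids, 10, replace=False))
            res = gsea_permutation(ranked, members, cfg,
                                   rng=np.random.default_rng(seed))
            if not res.flagged:
                vals.append(abs(res.nes))
        assert 0.85 <= np.mean(vals) <= 1.15

    def test_nes_stable_in_n_perm(self, small_cohort):
        discovery, _, _, truth = small_cohort
        stats = compute_group_stats(discovery)
        ranked = make_ranked_list(stats)
        up = sorted(f for f, d in truth.de_proteins.items() if d > 0)[:20]
        r1 = gsea_permutation(ranked, up, ConsistencyConfig(n_perm=1000, seed=9),
                              rng=np.random.default_rng(9))
        r2 = gsea_permutation(ranked, up, ConsistencyConfig(n_perm=2000, seed=9),
                              rng=np.random.default_rng(9))
        assert r1.es == r2.es
        assert abs(r1.nes - r2.nes) < 0.1

    def test_run_gsea_order_invariant(self, rng):
        ranked = ranked_from(np.sort(rng.normal(size=100))[::-1])
        sets = {f"S{i}": ("", list(rng.choice(ranked.ids, 8, replace=False)))
                for i in range(6)}
        cfg = ConsistencyConfig(n_perm=100, seed=4)
        t1 = run_gsea(ranked, GeneSetCollection(sets), cfg)
        rev = GeneSetCollection(dict(reversed(list(sets.items()))))
        t2 = run_gsea(ranked, rev, cfg)
        pd.testing.assert_frame_equal(t1.sort_index(), t2.sort_index())


def brute_force_consistency(tables, pct):
    """Exhaustive sign+percentile scan, independent of the implementation."""
    kept = []
    common = set.intersection(*(set(t.index[t["nes"].notna()])
                                for t in tables.values()))
    for name in common:
        signs = {np.sign(t.loc[name, "nes"]) for t in tables.values()}
        if len(signs) != 1 or 0 in signs:
            continue
        ok = True
        for t in tables.values():
            nes_all = t["nes"].dropna()
            x = t.loc[name, "nes"]
            if x > 0:
                frac = (nes_all > x).sum() / len(nes_all)
            else:
                frac = (nes_all < x).sum() / len(nes_all)
            if not frac < pct:
                ok = False
        if ok:
            kept.append(name)
    return sorted(kept)


class TestConsistencyFilter:
    def make_tables(self, rng, n=100, planted=8):
        names = [f"P{i:03d}" for i in range(n)]
        tables = {}
        base = rng.normal(0, 1, size=(3, n))
        for i in range(planted):
            sign = 1 if i % 2 == 0 else -1
            base[:, i] = sign * (4 + rng.random(3))
        for d, tag in enumerate(["a", "b", "c"]):
            tables[tag] = pd.DataFrame({"nes": base[d]}, index=names)
        return tables, names[:planted]

    def test_sign_mismatch_excluded(self):
        tables = {t: pd.DataFrame({"nes": [v, 1.0]}, index=["p", "filler"])
                  for t, v in zip("abc", [2.0, 2.0, -2.0])}
        names, _ = consistency_filter(tables, pct=0.5)
        assert "p" not in names

    def test_single_pathway_kept_when_signs_agree(self):
        tables = {t: pd.DataFrame({"nes": [1.5]}, index=["only"])
                  for t in "abc"}
        names, _ = consistency_filter(tables, pct=0.15)
        assert names == ["only"]

    def test_planted_extremes_match_brute_force(self, rng):
        tables, planted = self.make_tables(rng)
        names, _ = consistency_filter(tables, pct=0.15)
        assert names == sorted(planted)
        assert names == brute_force_consistency(tables, 0.15)

    def test_invariant_to_order_and_monotone_rescaling(self, rng):
        tables, _ = self.make_tables(rng)
        ref, _ = consistency_filter(tables, pct=0.15)
        shuffled = {t: tbl.sample(frac=1, random_state=1)
                    for t, tbl in tables.items()}
        assert consistency_filter(shuffled, pct=0.15)[0] == ref
        rescaled = {t: tbl.assign(nes=np.sinh(tbl["nes"] / 2))
                    for t, tbl in tables.items()}
        assert consistency_filter(rescaled, pct=0.15)[0] == ref
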