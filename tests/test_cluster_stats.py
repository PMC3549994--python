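import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from profclust.cluster_stats import (
    anova_by_cluster,
    bh_adjust,
    binomial_category_test,
    species_venn,
    summarize_clusters,
    term_enrichment,
    venn_to_tsv,
)
from profclust.graph_clustering import CLOUD, Clustering
from profclust.profiles import PhyloProfile, ProfileSet
from profclust.taxonomy import SpeciesUniverse


def profile_set(sets, lengths=None):
    universe = SpeciesUniverse.from_ids(sorted(set().union(*sets.values()) or {1}))
    profiles = [PhyloProfile.from_species_set(pid, s, universe) for pid, s in sets.items()]
    meta = None
    if lengths:
        meta = pd.DataFrame({"length": pd.Series(lengths)})
        meta.index.name = "protein_id"
    return ProfileSet(universe, profiles, meta)


class TestSummaries:
    def test_single_cluster_holds_whole_proteome(self):
        ps = profile_set({"a": {1, 2}, "b": {2, 3}}, {"a": 100, "b": 300})
        cl = Clustering({"a": "A", "b": "A"})
        (summary,) = summarize_clusters(cl, ps)
        assert summary.pct_of_proteome == 100.0
        assert summary.mean_protein_length == pytest.approx(200.0)
        assert summary.species_union == {1, 2, 3}

    def test_percentages_sum_to_100_and_union_matches_brute_force(self, planted):
        *_, ps, labels = planted
        summaries = summarize_clusters(Clustering(
            {p: (l if l != "cloud" else CLOUD) for p, l in labels.items()}), ps)
        assert sum(s.pct_of_proteome for s in summaries) == pytest.approx(100.0)
        for s in summaries:
            if s.label == CLOUD:
                continue
            members = [p for p, l in labels.items() if l == s.label]
            brute = set()
            for pid in members:
                brute |= ps.species_of_protein(pid)
            assert s.species_union == brute
            assert s.hit_count_min <= s.hit_count_median <= s.hit_count_max


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        cl = Clustering({f"p{i}": "A" for i in range(3)} | {f"q{i}": "B" for i in range(3)})
        vals = {"p0": 1, "p1": 2, "p2": 3, "q0": 1, "q1": 2, "q2": 3}
        f, p, means = anova_by_cluster(cl, vals)
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert means == {"A": 2.0, "B": 2.0}

    def test_two_groups_f_equals_t_squared(self, rng):
        a = rng.normal(10, 2, 12)
        b = rng.normal(12, 2, 15)
        cl = Clustering({f"a{i}": "A" for i in range(12)} | {f"b{i}": "B" for i in range(15)})
        vals = {f"a{i}": a[i] for i in range(12)} | {f"b{i}": b[i] for i in range(15)}
        f, p, _ = anova_by_cluster(cl, vals)
        t, pt = sps.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t**2)
        assert p == pytest.approx(pt)

    def test_three_groups_match_sum_of_squares_oracle(self, rng):
        groups = {"A": rng.normal(5, 1, 8), "B": rng.normal(6, 1, 10), "C": rng.normal(4, 1, 6)}
        assignment, vals = {}, {}
        for g, arr in groups.items():
            for i, x in enumerate(arr):
                assignment[f"{g}{i}"] = g
                vals[f"{g}{i}"] = float(x)
        f, p, _ = anova_by_cluster(Clustering(assignment), vals)
        # brute-force between/within sum of squares
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in groups.values())
        ss_within = sum(((a - a.mean()) ** 2).sum() for a in groups.values())
        df_b, df_w = 2, len(allv) - 3
        f_oracle = (ss_between / df_b) / (ss_within / df_w)
        assert f == pytest.approx(f_oracle)
        assert p == pytest.approx(float(sps.f.sf(f_oracle, df_b, df_w)))

    def test_shift_and_scale_invariance(self, rng):
        assignment = {f"a{i}": "A" for i in range(5)} | {f"b{i}": "B" for i in range(5)}
        vals = {k: float(v) for k, v in zip(assignment, rng.normal(0, 1, 10))}
        f0, _, _ = anova_by_cluster(Clustering(assignment), vals)
        f1, _, _ = anova_by_cluster(Clustering(assignment), {k: v + 100 for k, v in vals.items()})
        f2, _, _ = anova_by_cluster(Clustering(assignment), {k: v * 7 for k, v in vals.items()})
        assert f1 == pytest.approx(f0)
        assert f2 == pytest.approx(f0)

    def test_small_group_is_an_error(self):
        cl = Clustering({"a": "A", "b": "B", "c": "B"})
        with pytest.raises(ValueError, match="'A'"):
            anova_by_cluster(cl, {"a": 1.0, "b": 2.0, "c": 3.0})


class TestBinomial:
    def test_closed_form_tails(self):
        assert binomial_category_test(0, 10, 0.5, "less") == pytest.approx(2**-10)
        assert binomial_category_test(7, 7, 0.5, "greater") == pytest.approx(2**-7)

    def test_matches_direct_mass_summation(self):
        k, n, p0 = 14, 54, 210 / 1410
        oracle = sum(math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(k, n + 1))
        assert binomial_category_test(k, n, p0, "greater") == pytest.approx(oracle)

    def test_tails_overlap_at_point_mass(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 40))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.05, 0.95))
            lo = binomial_category_test(k, n, p0, "less")
            hi = binomial_category_test(k, n, p0, "greater")
            assert lo + hi >= 1.0 - 1e-12

    def test_invalid_p0_rejected(self):
        with pytest.raises(ValueError, match="p0"):
            binomial_category_test(1, 10, 0.0)


class TestVenn:
    @staticmethod
    def clustered_sets(sets):
        ps = profile_set({f"{lbl}{i}": s for lbl, ss in sets.items() for i, s in enumerate(ss)})
        cl = Clustering({f"{lbl}{i}": lbl for lbl, ss in sets.items() for i in range(len(ss))})
        return ps, cl

    def test_identical_sets_only_intersection(self):
        ps, cl = self.clustered_sets({"A": [{1, 2, 3}], "B": [{1, 2, 3}]})
        regions = species_venn(cl, ps, ["A", "B"])
        assert regions[frozenset({"A", "B"})] == 3
        assert regions[frozenset({"A"})] == 0
        assert regions[frozenset({"B"})] == 0

    def test_disjoint_sets(self):
        ps, cl = self.clustered_sets({"A": [{1, 2, 3}], "B": [{4, 5, 6, 7, 8}]})
        regions = species_venn(cl, ps, ["A", "B"])
        assert regions[frozenset({"A"})] == 3
        assert regions[frozenset({"B"})] == 5
        assert regions[frozenset({"A", "B"})] == 0

    def test_random_four_sets_match_enumeration_and_partition(self, rng):
        for _ in range(5):
            unions = {lbl: set(map(int, rng.choice(60, rng.integers(5, 40), replace=False)))
                      for lbl in "ABCD"}
            ps, cl = self.clustered_sets({lbl: [s] for lbl, s in unions.items()})
            regions = species_venn(cl, ps, list("ABCD"))
            assert len(regions) == 15
            # per-species enumeration oracle
            for labels_subset, count in regions.items():
                expect = sum(
                    1
                    for s in set().union(*unions.values())
                    if {l for l in "ABCD" if s in unions[l]} == set(labels_subset)
                )
                assert count == expect
            assert sum(regions.values()) == len(set().union(*unions.values()))

    def test_more_than_four_clusters_rejected(self):
        ps, cl = self.clustered_sets({lbl: [{1}] for lbl in "ABCDE"})
        with pytest.raises(ValueError, match="at most 4"):
            species_venn(cl, ps, list("ABCDE"))

    def test_tsv_region_bitmask(self):
        ps, cl = self.clustered_sets({"A": [{1, 2}], "B": [{2}]})
        text = venn_to_tsv(species_venn(cl, ps, ["A", "B"]), ["A", "B"])
        assert "10\tA\t1" in text
        assert "11\tA&B\t1" in text


def hypergeom_oracle(k, N, K, m):
    """Upper-tail P(X >= k) by direct combinatorial summation."""
    return sum(
        math.comb(K, i) * math.comb(N - K, m - i) / math.comb(N, m)
        for i in range(k, min(K, m) + 1)
    )


class TestEnrichment:
    @staticmethod
    def build(cluster_terms, background_terms):
        """cluster_terms/background_terms: protein -> set of terms."""
        members = set(cluster_terms)
        background = set(cluster_terms) | set(background_terms)
        cl = Clustering({p: ("A" if p in members else CLOUD) for p in background})
        return cl, {**background_terms, **cluster_terms}, background

    def test_fold_enrichment_two_when_term_universal_in_cluster(self):
        cluster = {f"c{i}": {"T"} for i in range(10)}
        rest = {f"r{i}": ({"T"} if i < 40 else set()) for i in range(90)}
        cl, ann, bg = self.build(cluster, rest)
        (res,) = term_enrichment(cl, "A", ann, bg)
        assert res.fold_enrichment == pytest.approx(2.0)   # (10/10)/(50/100)
        assert res.percent == pytest.approx(100.0)

    def test_fold_one_when_frequency_matches_background(self):
        cluster = {f"c{i}": ({"T"} if i < 2 else set()) for i in range(10)}
        rest = {f"r{i}": ({"T"} if i < 18 else set()) for i in range(90)}
        cl, ann, bg = self.build(cluster, rest)
        (res,) = term_enrichment(cl, "A", ann, bg)
        assert res.fold_enrichment == pytest.approx(1.0)
        assert res.p_raw > 0.3

    def test_pvalue_matches_combinatorial_enumeration(self):
        # Nbg=20, K=5 annotated, cluster m=8 with k=4 annotated
        cluster = {f"c{i}": ({"T"} if i < 4 else set()) for i in range(8)}
        rest = {f"r{i}": ({"T"} if i < 1 else set()) for i in range(12)}
        cl, ann, bg = self.build(cluster, rest)
        (res,) = term_enrichment(cl, "A", ann, bg)
        assert res.p_raw == pytest.approx(hypergeom_oracle(4, 20, 5, 8))

    def test_adjusted_p_at_least_raw_and_sorted(self, rng):
        cluster = {f"c{i}": {f"T{j}" for j in range(int(rng.integers(1, 6)))} for i in range(12)}
        rest = {f"r{i}": {f"T{j}" for j in np.flatnonzero(rng.random(6) < 0.3)} for i in range(50)}
        cl, ann, bg = self.build(cluster, rest)
        results = term_enrichment(cl, "A", ann, bg)
        assert all(r.p_adjusted >= r.p_raw - 1e-12 for r in results)
        assert [r.p_adjusted for r in results] == sorted(r.p_adjusted for r in results)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            term_enrichment(Clustering({}), "A", {}, set())

    def test_cluster_outside_background_rejected(self):
        cl = Clustering({"a": "A"})
        with pytest.raises(ValueError, match="subset"):
            term_enrichment(cl, "A", {}, {"b"})


class TestBH:
    def test_monotone_in_rank_and_bounded(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, int(rng.integers(1, 30)))
            adj = bh_adjust(p)
            order = np.argsort(p)
            assert (np.diff(adj[order]) >= -1e-12).all()
            assert ((adj >= p - 1e-12) & (adj <= 1 + 1e-12)).all()

    def test_constant_vectors_are_fixed_points(self, rng):
        for c in (0.01, 0.2, 1.0):
            p = np.full(8, c)
            assert np.allclose(bh_adjust(p), p)
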