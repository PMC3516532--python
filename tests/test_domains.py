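"""Domain retention, categorization, co-occurrence testing, clustering, networks."""

from itertools import permutations

import numpy as np
import pytest

from tpghallmarks.domains import (
    BernoulliMixture,
    breakpoint_nt_to_aa,
    build_interactor_network,
    cluster_functional_profiles,
    cooccurrence_counts,
    cooccurrence_permutation_test,
    fit_bernoulli_mixture,
    fusion_network_edges,
    partner_category_set,
    retained_and_lost,
    type_dependency_test,
    FusionProfile,
)
from tpghallmarks.models import CategoryMap, DomainAnnotation, Translocation

F = frozenset


def dom(gene, fid, a, b, pii=False, partners=()):
    return DomainAnnotation(gene, fid, a, b, is_pii=pii,
                            partners=frozenset(partners))


class TestBreakpointConversion:
    @pytest.mark.parametrize("bp,cds,expected", [
        (100, 100, (1, False)),
        (103, 100, (2, False)),
        (50, 100, (0, True)),     # upstream of CDS: clamp and flag
    ])
    def test_nt_to_aa(self, bp, cds, expected):
        assert breakpoint_nt_to_aa(bp, cds) == expected


class TestRetention:
    DOMAINS = [dom("G", "d1", 10, 100), dom("G", "d2", 150, 290),
               dom("G", "d3", 280, 350), dom("G", "d4", 400, 500)]

    def test_five_prime_keeps_entirely_upstream(self):
        r = retained_and_lost(self.DOMAINS, 300, "five_prime")
        assert {d.feature_id for d in r.retained} == {"d1", "d2"}
        assert {d.feature_id for d in r.lost} == {"d3", "d4"}

    def test_three_prime_keeps_entirely_downstream(self):
        r = retained_and_lost(self.DOMAINS, 300, "three_prime")
        assert {d.feature_id for d in r.retained} == {"d4"}

    def test_clamped_breakpoint_three_prime_keeps_all(self):
        r = retained_and_lost(self.DOMAINS, 0, "three_prime")
        assert len(r.retained) == 4 and not r.lost

    def test_accounting_identity_on_synthetic_fusions(self, small_bundle):
        """retained + lost = all annotations, for every fusion and side."""
        from tpghallmarks.domains import fusion_profiles
        by = {}
        for a in small_bundle.annotations:
            by.setdefault(a.gene_id, []).append(a)
        cds = {g: m.cds_start_nt for g, m in small_bundle.catalog.items()}
        _, retentions = fusion_profiles(small_bundle.translocations, by, cds,
                                        small_bundle.cmap)
        for fid, sides in retentions.items():
            for side, rec in sides.items():
                both = rec.retained + rec.lost
                if both:
                    src = by[both[0].gene_id]
                    assert len(rec.retained) + len(rec.lost) == len(src)
                    assert not (set(map(id, rec.retained))
                                & set(map(id, rec.lost)))


class TestCategorySet:
    CMAP = CategoryMap({"d1": "D", "d2": "O", "d3": "O"})

    def rec(self, retained):
        from tpghallmarks.domains import RetentionRecord
        return RetentionRecord("F", "five_prime", retained, [], 100)

    def test_mixed_set_is_type1(self):
        s, t = partner_category_set(self.rec([dom("G", "d1", 1, 5),
                                              dom("G", "d2", 6, 9)]), self.CMAP)
        assert s == F({"D", "O"}) and t == 1

    def test_empty_encodes_as_N_type2(self):
        s, t = partner_category_set(self.rec([]), self.CMAP)
        assert s == F({"N"}) and t == 2

    def test_only_other_is_type2(self):
        s, t = partner_category_set(self.rec([dom("G", "d3", 1, 5)]), self.CMAP)
        assert s == F({"O"}) and t == 2

    def test_pii_does_not_set_categories(self):
        s, t = partner_category_set(
            self.rec([dom("G", "p1", 1, 5, pii=True, partners=["X"])]), self.CMAP)
        assert s == F({"N"}) and t == 2

    def test_unmapped_feature_raises(self):
        with pytest.raises(KeyError):
            partner_category_set(self.rec([dom("G", "zz", 1, 5)]), self.CMAP)


class TestCooccurrenceCounts:
    def test_multi_category_sets_expand(self):
        C = cooccurrence_counts([F("D"), F("DP"), F("N")],
                                [F("P"), F("P"), F("K")])
        idx = {c: i for i, c in enumerate("DPHKON")}
        assert C[idx["D"], idx["P"]] == 2
        assert C[idx["P"], idx["P"]] == 1
        assert C[idx["N"], idx["K"]] == 1
        assert C.sum() == 4

    def test_single_nn_translocation(self):
        C = cooccurrence_counts([F("N")], [F("N")])
        assert C[5, 5] == 1 and C.sum() == 1

    def test_margin_counting_identity(self, rng):
        cats = list("DPHKO")
        set5s = [F(rng.choice(cats, size=rng.integers(1, 4), replace=False))
                 for _ in range(40)]
        set3s = [F(rng.choice(cats, size=1)) for _ in range(40)]
        C = cooccurrence_counts(set5s, set3s)
        idx = {c: i for i, c in enumerate("DPHKON")}
        for c5 in cats:
            with_c5 = sum(c5 in s for s in set5s)
            # |set3| = 1 everywhere, so the row sum equals the 5' margin
            assert C[idx[c5]].sum() == with_c5


class TestCooccurrencePermutation:
    def test_single_translocation_all_p_one(self):
        res = cooccurrence_permutation_test([F("D")], [F("P")], n_perm=200, seed=0)
        assert np.all(res.p_value[res.tested] == 1.0)

    def test_matches_exhaustive_enumeration(self):
        """Monte-Carlo p within 3 SE of the exact value over all 3! pairings."""
        set5s = [F("D"), F("P"), F("N")]
        set3s = [F("K"), F("D"), F("O")]
        res = cooccurrence_permutation_test(set5s, set3s, n_perm=20_000, seed=5)
        A = np.array([[c in s for c in "DPHKON"] for s in set5s], float)
        B = np.array([[c in s for c in "DPHKON"] for s in set3s], float)
        obs = A.T @ B
        exact_stats = np.stack([A.T @ B[list(p)] for p in permutations(range(3))])
        n_enum = exact_stats.shape[0]
        p_ge = (exact_stats >= obs).sum(0) / n_enum
        p_le = (exact_stats <= obs).sum(0) / n_enum
        exact = np.minimum(1.0, 2 * np.minimum(p_ge, p_le))
        for i in range(6):
            for j in range(6):
                if not res.tested[i, j]:
                    continue
                # the two-sided p doubles one tail, so its MC error is twice
                # the binomial SE of that tail
                q = min(p_ge[i, j], p_le[i, j])
                se = 2 * np.sqrt(max(q * (1 - q), 1e-9) / 20_000)
                assert abs(res.p_value[i, j] - exact[i, j]) <= 3 * se + 2 / 20_000

    def test_invariant_category_fold_exactly_one(self):
        """A category present in every 3' set is invariant under exchange."""
        set5s = [F("D"), F("P"), F("N"), F("DO")]
        set3s = [F("K"), F("KO"), F("K"), F("KD")]
        res = cooccurrence_permutation_test(set5s, set3s, n_perm=500, seed=1)
        idx = {c: i for i, c in enumerate("DPHKON")}
        for c5 in "DPN":
            assert res.fold[idx[c5], idx["K"]] == 1.0

    def test_null_preserves_marginal_multisets(self):
        """The shuffle null reorders the same multiset of 3' sets, so with
        singleton 3' sets both row and column margins of every permuted
        count matrix are fixed."""
        set5s = [F("D"), F("DP"), F("N"), F("O"), F("PK")]
        set3s = [F("K"), F("N"), F("P"), F("K"), F("O")]   # all |set3| = 1
        from tpghallmarks.domains import _indicator, _permuted_counts
        A, B = _indicator(set5s), _indicator(set3s)
        null = _permuted_counts(A, B, 50, np.random.default_rng(0))
        obs = A.T @ B
        # row margin: each translocation contributes |set5 row| once
        assert np.allclose(null.sum(axis=2), obs.sum(axis=1)[None, :])
        # column margin: 3' multiset fixed, weighted by total 5' memberships
        assert np.allclose(null.sum(axis=(1, 2)), obs.sum())


class TestTypeDependency:
    def test_zero_margin_skipped(self):
        profiles = [FusionProfile(f"F{i}", F("D"), F("K"), 1, 1) for i in range(10)]
        res = type_dependency_test(profiles, n_perm=100, seed=0)
        assert res.skipped and res.type2_type2_fraction == 0.0

    def test_balanced_table_p_one(self):
        profiles = []
        for i, (t5, t3) in enumerate([(1, 1), (1, 2), (2, 1), (2, 2)] * 2):
            s5 = F("D") if t5 == 1 else F("O")
            s3 = F("K") if t3 == 1 else F("N")
            profiles.append(FusionProfile(f"F{i}", s5, s3, t5, t3))
        res = type_dependency_test(profiles, n_perm=2000, seed=0)
        assert res.fisher_p == pytest.approx(1.0)

    def test_planted_dependence_detected(self, rng):
        """5' type 1 preferentially pairs with 3' type 2."""
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            profiles = []
            for i in range(300):
                t5 = 1 if r.random() < 0.5 else 2
                p_t2 = 0.7 if t5 == 1 else 0.3
                t3 = 2 if r.random() < p_t2 else 1
                profiles.append(FusionProfile(
                    f"F{i}", F("D") if t5 == 1 else F("N"),
                    F("N") if t3 == 2 else F("K"), t5, t3))
            res = type_dependency_test(profiles, n_perm=200, seed=seed)
            hits += res.fisher_p < 0.05
        assert hits >= 18


class TestBernoulliMixtureEM:
    def test_m_step_identity_single_component(self, rng):
        """With k=1 the fitted probabilities are the clamped bit means."""
        X = (rng.random((80, 10)) < 0.3).astype(float)
        m = fit_bernoulli_mixture(X, 1, rng, n_restarts=2)
        assert np.allclose(m.probs[0], np.clip(X.mean(0), 1e-4, 1 - 1e-4),
                           atol=1e-6)

    def test_cluster_probs_reproduce_clusterwise_bit_means(self, rng):
        X = np.vstack([(rng.random((60, 10)) < [0.9] * 5 + [0.1] * 5),
                       (rng.random((60, 10)) < [0.1] * 5 + [0.9] * 5)]).astype(float)
        m = fit_bernoulli_mixture(X, 2, rng, n_restarts=5)
        r = m.responsibilities(X)
        for c in range(2):
            weighted = (r[:, c:c + 1] * X).sum(0) / r[:, c].sum()
            assert np.allclose(m.probs[c], np.clip(weighted, 1e-4, 1 - 1e-4),
                               atol=1e-6)

    def test_identical_profiles_select_k1(self):
        X = np.tile(np.array([1, 0, 1, 0, 0, 1, 0, 0, 0, 0], float), (30, 1))
        res = cluster_functional_profiles(X, seed=0, max_k=4)
        assert res.k == 1

    def test_deterministic_given_seed(self, rng):
        X = (rng.random((50, 10)) < 0.4).astype(float)
        a = cluster_functional_profiles(X, seed=42, max_k=3)
        b = cluster_functional_profiles(X, seed=42, max_k=3)
        assert a.k == b.k
        assert np.array_equal(a.assignments, b.assignments)
        assert np.allclose(a.cluster_probs, b.cluster_probs)

    def test_probabilities_within_bounds(self, rng):
        X = (rng.random((40, 10)) < 0.5).astype(float)
        res = cluster_functional_profiles(X, seed=3, max_k=3)
        assert np.all(res.cluster_probs >= 0) and np.all(res.cluster_probs <= 1)


class TestNetworks:
    def make_retentions(self):
        from tpghallmarks.domains import RetentionRecord
        kept = dom("G3", "pii1", 10, 30, pii=True, partners=["X", "Y"])
        lost = dom("G3", "pii2", 200, 240, pii=True, partners=["Z"])
        rec = RetentionRecord("F1", "three_prime", [kept], [lost], 100)
        kept_b = dom("G4", "pii3", 5, 20, pii=True, partners=["X"])
        rec_b = RetentionRecord("F2", "three_prime", [kept_b], [], 50)
        return {"F1": {"three_prime": rec}, "F2": {"three_prime": rec_b}}

    def test_edges_only_through_retained_piis(self):
        edges, multiset = build_interactor_network(self.make_retentions())
        targets = {(e[0], e[1]) for e in edges}
        assert ("G3", "X") in targets and ("G3", "Y") in targets
        assert ("G3", "Z") not in targets  # lost PII contributes nothing

    def test_partner_multiset_preserves_multiplicity(self):
        _, multiset = build_interactor_network(self.make_retentions())
        assert multiset.count("X") == 2  # X interacts with two TPGs

    def test_fusion_network_variant_counts(self):
        ts = [Translocation("F1", "A", "B", 10, 20, "HEM-L", 1),
              Translocation("F2", "A", "B", 30, 40, "HEM-L", 1),
              Translocation("F3", "A", "C", 10, 20, "HEM-M", 2)]
        edges = fusion_network_edges(ts, {"F1": 0, "F2": 0, "F3": 1})
        assert ("A", "B", 0, 2) in edges and ("A", "C", 1, 1) in edges
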