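"""Synthetic-data generator: determinism, invariants, planted-effect checks."""

import numpy as np
import pytest

from tpghallmarks.domains import fusion_profiles
from tpghallmarks.simulate import (
    SimulationConfig,
    gene_central_flags,
    simulate_bundle,
    simulate_contact_matrix,
    simulate_expression_and_tracks,
    simulate_genome,
    simulate_rt_profile,
    simulate_translocation_set,
)


def profiles_of(config, seed_offset=0):
    rng = np.random.default_rng(config.seed + seed_offset)
    cat, cmap, anns = simulate_genome(config, rng)
    ts = simulate_translocation_set(config, cat, anns, cmap, rng)
    by = {}
    for a in anns:
        by.setdefault(a.gene_id, []).append(a)
    cds = {g: m.cds_start_nt for g, m in cat.items()}
    profs, _ = fusion_profiles(ts, by, cds, cmap)
    return ts, profs


class TestGenome:
    def test_deterministic_given_seed(self, small_config):
        a = simulate_genome(small_config)
        b = simulate_genome(small_config)
        assert a[0] == b[0]
        assert dict(a[1]) == dict(b[1])
        assert a[2] == b[2]

    def test_counts_and_coverage(self):
        cfg = SimulationConfig(seed=0, n_genes=100, n_chrom=5, n_bins=100)
        catalog, _, _ = simulate_genome(cfg)
        assert len(catalog) == 100
        assert {g.chrom for g in catalog.values()} == {f"chr{i}" for i in range(1, 6)}

    def test_utr_within_gene_span(self, small_bundle):
        for g in small_bundle.catalog.values():
            if g.has_utr3:
                assert g.tx_start <= g.utr3_start < g.utr3_end <= g.tx_end

    def test_too_dense_genome_rejected(self):
        cfg = SimulationConfig(seed=0, n_genes=100_000, n_chrom=2, n_bins=10,
                               bin_size=100_000)
        with pytest.raises(ValueError, match="too small"):
            simulate_genome(cfg)


class TestTranslocations:
    def test_breakpoints_inside_cds(self, small_bundle):
        for t in small_bundle.translocations:
            g5 = small_bundle.catalog[t.five_gene]
            assert t.five_bp_nt >= g5.cds_start_nt

    def test_null_fold_matrix_independence(self):
        """With all folds 1 the (c5, c3) counts match the independence
        expectation from the realized marginals within 3 SE."""
        cfg = SimulationConfig(seed=3, n_genes=800, n_transloc=3000)
        _, profs = profiles_of(cfg)
        n = len(profs)
        cats = "DPHKON"
        A = np.array([[c in p.set5 for c in cats] for p in profs], float)
        B = np.array([[c in p.set3 for c in cats] for p in profs], float)
        C = A.T @ B
        m5, m3 = A.mean(0), B.mean(0)
        for i in range(6):
            for j in range(6):
                exp = n * m5[i] * m3[j]
                if exp < 5:
                    continue
                se = np.sqrt(exp)
                assert abs(C[i, j] - exp) <= 4 * se, (cats[i], cats[j])

    def test_planted_fold_realized(self):
        """Planted 3-fold (O,K) cell exceeds twice the independence
        expectation in most replicates."""
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, cooccurrence_folds={"O,K": 3.0})
            _, profs = profiles_of(cfg)
            A = np.array([["O" in p.set5] for p in profs], float)
            B = np.array([["K" in p.set3] for p in profs], float)
            obs = float((A[:, 0] * B[:, 0]).sum())
            exp = len(profs) * A.mean() * B.mean()
            hits += obs >= 2 * exp
        assert hits >= 9

    def test_infeasible_fold_rejected(self):
        cfg = SimulationConfig(seed=0, n_genes=200, n_transloc=50,
                               cooccurrence_folds={"D,P": 500.0})
        rng = np.random.default_rng(0)
        cat, cmap, anns = simulate_genome(cfg, rng)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_translocation_set(cfg, cat, anns, cmap, rng)

    def test_large_zipf_exponent_mostly_single_reports(self):
        cfg = SimulationConfig(seed=1, n_genes=300, n_bins=100, n_transloc=200,
                               zipf_exponent=8.0)
        ts, _ = profiles_of(cfg)
        assert np.mean([t.report_count == 1 for t in ts]) > 0.95


class TestContactMatrix:
    def test_symmetry_and_nonnegativity(self, small_bundle):
        v = small_bundle.matrix_a.values
        assert np.allclose(v, v.T)
        assert np.all(v >= 0)

    def test_zero_boost_no_compartment_signal(self):
        cfg = SimulationConfig(seed=4, contact_boost=0.0, n_bins=200)
        m, central = simulate_contact_matrix(cfg)
        trans = m.trans_mask()
        c_mean = m.values[np.ix_(central, ~central)][
            trans[np.ix_(central, ~central)]].mean()
        vals_c = m.values[np.ix_(central, central)]
        vals_p = m.values[np.ix_(~central, ~central)]
        tc = trans[np.ix_(central, central)]
        tp = trans[np.ix_(~central, ~central)]
        assert abs(vals_c[tc].mean() - vals_p[tp].mean()) < 0.1

    def test_boosted_central_bins_higher_trans_contact(self):
        for seed in range(5):
            cfg = SimulationConfig(seed=seed, contact_boost=5.0,
                                   contact_noise_sigma=0.1)
            m, central = simulate_contact_matrix(cfg)
            trans = m.trans_mask()
            vals = np.where(trans, m.values, np.nan)
            mean_c = np.nanmean(vals[central])
            mean_p = np.nanmean(vals[~central])
            assert mean_c > mean_p


class TestRtProfile:
    def test_positions_strictly_increasing(self, small_bundle):
        for chrom, (pos, _) in small_bundle.rt_profile.data.items():
            assert np.all(np.diff(pos) > 0)

    def test_zero_correlation_parameter(self):
        cfg = SimulationConfig(seed=5, rt_centrality_corr=0.0, n_bins=500)
        rng = np.random.default_rng(5)
        m, central = simulate_contact_matrix(cfg, rng)
        prof = simulate_rt_profile(cfg, m, central, rng)
        from tpghallmarks.spatial import bin_centrality
        cent = bin_centrality(m)
        rt_vals = np.concatenate([prof.data[c][1] for c in sorted(prof.data)])
        # bins are genome-ordered in both structures
        order = np.concatenate([m.bins.index[m.bins["chrom"] == c].to_numpy()
                                for c in sorted(prof.data)])
        from scipy.stats import spearmanr
        r = spearmanr(cent[order], rt_vals).statistic
        assert abs(r) < 0.15

    def test_strong_correlation_parameter(self):
        cfg = SimulationConfig(seed=6, rt_centrality_corr=0.9, n_bins=500)
        rng = np.random.default_rng(6)
        m, central = simulate_contact_matrix(cfg, rng)
        prof = simulate_rt_profile(cfg, m, central, rng)
        from tpghallmarks.spatial import bin_centrality
        from scipy.stats import spearmanr
        cent = bin_centrality(m)
        order = np.concatenate([m.bins.index[m.bins["chrom"] == c].to_numpy()
                                for c in sorted(prof.data)])
        rt_vals = np.concatenate([prof.data[c][1] for c in sorted(prof.data)])
        assert spearmanr(cent[order], rt_vals).statistic > 0.7


class TestExpressionAndTracks:
    def test_zero_shift_calibrated(self):
        """Without a planted shift, the 5' TPG HEM contrast is null."""
        from scipy.stats import mannwhitneyu
        from tpghallmarks.expression import aggregate_by_tissue
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, n_genes=300, n_bins=100,
                                   n_transloc=60, expression_shift=0.0)
            rng = np.random.default_rng(seed)
            cat, cmap, anns = simulate_genome(cfg, rng)
            ts = simulate_translocation_set(cfg, cat, anns, cmap, rng)
            expr, *_ = simulate_expression_and_tracks(cfg, cat, ts, rng)
            _, groups = aggregate_by_tissue(expr)
            five = sorted({t.five_gene for t in ts})
            bg = [g for g in groups.index if g not in five]
            p = mannwhitneyu(groups.loc[five, "HEM"], groups.loc[bg, "HEM"]).pvalue
            hits += p >= 0.05
        assert hits >= 8

    def test_planted_shift_size(self):
        """Planted log2 shift of 1 appears in paired 5'-3' differences."""
        cfg = SimulationConfig(seed=9, n_genes=600, n_transloc=200,
                               expression_shift=1.0)
        rng = np.random.default_rng(9)
        cat, cmap, anns = simulate_genome(cfg, rng)
        ts = simulate_translocation_set(cfg, cat, anns, cmap, rng)
        expr, *_ = simulate_expression_and_tracks(cfg, cat, ts, rng)
        from tpghallmarks.expression import aggregate_by_tissue
        _, groups = aggregate_by_tissue(expr)
        d = [groups.loc[t.five_gene, "HEM"] - groups.loc[t.five_gene, ["EPI", "MES"]].mean()
             for t in ts]
        assert abs(np.median(d) - 1.0) < 0.2

    def test_utr_shortening_ratio(self, small_bundle):
        """3' TPG UTRs end up near the configured fraction of the 5'-side
        length distribution."""
        three = {t.three_gene for t in small_bundle.translocations}
        five_only = {t.five_gene for t in small_bundle.translocations} - three
        l3 = [small_bundle.catalog[g].utr3_length for g in three
              if small_bundle.catalog[g].has_utr3]
        l5 = [small_bundle.catalog[g].utr3_length for g in five_only
              if small_bundle.catalog[g].has_utr3]
        ratio = np.median(l3) / np.median(l5)
        assert 0.3 < ratio < 0.75   # configured 0.5 with sampling noise

    def test_peaks_valid_bed(self, small_bundle):
        for track in small_bundle.pol2_tracks.values():
            for r in track:
                assert r.start < r.end


class TestBundle:
    def test_identical_seeds_identical_truth(self, small_config):
        a = simulate_bundle(small_config)
        b = simulate_bundle(small_config)
        assert a.truth == b.truth
        assert np.array_equal(a.matrix_a.values, b.matrix_a.values)

    def test_central_flags_match_truth(self, small_bundle):
        flags = gene_central_flags(small_bundle.catalog, small_bundle.matrix_a,
                                   small_bundle.central_mask)
        assert set(flags) == set(small_bundle.catalog)
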