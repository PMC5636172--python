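import numpy as np
import pytest

from dosagekin.kinship_hom import gcta_estimator
from dosagekin.simulate import (
    SimConfig,
    apply_variant_filters,
    build_pedigree,
    drop_genes,
    emulate_imputation,
    pedigree_kinship,
    simulate_dataset,
    simulate_founders,
    true_degree_labels,
)

from conftest import random_panel


def families_only(**kw):
    base = dict(
        n_snps=1000, n_trios=0, n_fullsib_families=0, n_second_degree_units=0,
        n_first_cousin_units=0, n_inbred_units=0, n_unrelated=0, n_reference=0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestFounders:
    def test_pure_ancestry_gives_subpop_frequency(self):
        cfg = families_only(n_unrelated=5, admixture=(1.0, 0.0))
        _, p_sub, admix, q, _ = simulate_founders(cfg, seed=0)
        np.testing.assert_allclose(q, np.tile(p_sub[0], (5, 1)))

    def test_fst_zero_means_no_drift(self):
        cfg = families_only(n_unrelated=4, fst=0.0)
        p_anc, p_sub, *_ = simulate_founders(cfg, seed=0)
        np.testing.assert_array_equal(p_sub[0], p_anc)
        np.testing.assert_array_equal(p_sub[1], p_anc)

    def test_balding_nichols_variance_matches_fst(self):
        # Var(p_k) = F p (1 - p): normalized squared drift averages to F
        cfg = families_only(n_unrelated=2, n_snps=10_000, fst=0.1)
        p_anc, p_sub, *_ = simulate_founders(cfg, seed=1)
        z = (p_sub[0] - p_anc) ** 2 / (p_anc * (1 - p_anc))
        assert z.mean() == pytest.approx(0.1, abs=0.01)

    def test_admixture_rows_sum_to_one(self):
        cfg = families_only(n_trios=3, n_unrelated=5)
        _, _, admix, _, _ = simulate_founders(cfg, seed=2)
        np.testing.assert_allclose(admix.sum(axis=1), 1.0, atol=1e-12)


class TestGeneDropping:
    def test_homozygous_parents_force_child_genotype(self):
        ped = build_pedigree(families_only(n_trios=1))
        g = np.array([[2, 0], [2, 2], [-1, -1]], dtype=np.int8)
        child = drop_genes(ped, g, seed=0)[2]
        assert child[0] == 2 and child[1] == 1

    def test_parent_offspring_kinship_recovered_from_genotypes(self):
        cfg = families_only(n_trios=12, n_unrelated=60, n_snps=20_000,
                            n_subpops=1, fst=0.0)
        truth, _ = simulate_dataset(cfg, seed=3)
        res = gcta_estimator(truth.genotypes.astype(float),
                             allele_freqs=truth.ancestral_freq)
        po = [res.phi[i, j] for (i, j), lab in
              true_degree_labels(truth.kinship).items() if lab == "PO/FS"]
        assert np.mean(po) == pytest.approx(0.25, abs=0.01)

    def test_duplicated_individual_estimates_half(self):
        cfg = families_only(n_unrelated=50, n_snps=20_000, n_subpops=1, fst=0.0)
        truth, _ = simulate_dataset(cfg, seed=4)
        g = np.vstack([truth.genotypes, truth.genotypes[:1]])  # MZ copy of s0
        res = gcta_estimator(g.astype(float), allele_freqs=truth.ancestral_freq)
        assert res.phi[0, 50] == pytest.approx(0.5, abs=0.01)

    def test_missing_parent_genotype_is_an_error(self):
        ped = build_pedigree(families_only(n_trios=1))
        g = np.array([[2], [-1], [-1]], dtype=np.int8)
        with pytest.raises(ValueError, match="no genotypes"):
            drop_genes(ped, g, seed=0)


class TestPedigreeKinship:
    def test_template_values_are_the_textbook_coefficients(self):
        cfg = families_only(n_trios=1, n_fullsib_families=1,
                            n_second_degree_units=1, n_first_cousin_units=1,
                            n_inbred_units=1, n_unrelated=1)
        ped = build_pedigree(cfg)
        phi = pedigree_kinship(ped)
        ids = {s: k for k, s in enumerate(ped["id"])}
        assert phi[ids["trio0_F"], ids["trio0_C"]] == 0.25
        assert phi[ids["fs0_C1"], ids["fs0_C2"]] == 0.25
        assert phi[ids["g2_0_GF"], ids["g2_0_C"]] == 0.125
        assert phi[ids["cz0_CA"], ids["cz0_CB"]] == 0.0625
        assert phi[ids["cz0_A"], ids["cz0_CB"]] == 0.125  # avuncular
        assert phi[ids["ib0_I"], ids["ib0_I"]] == 0.625  # f = 0.25
        assert phi[ids["ib0_A"], ids["ib0_I"]] == 0.375
        assert phi[ids["un0"], ids["trio0_C"]] == 0.0

    def test_matches_allele_dropping_monte_carlo_oracle(self):
        """Independent oracle: drop distinct founder allele labels through the
        inbred-loop pedigree and count identical-by-descent draws."""
        cfg = families_only(n_inbred_units=1)
        ped = build_pedigree(cfg)
        phi = pedigree_kinship(ped)
        rng = np.random.default_rng(5)
        n_reps = 40_000
        fa = ped["father"].to_numpy()
        mo = ped["mother"].to_numpy()
        alleles = np.empty((len(ped), 2, n_reps), dtype=np.int64)
        label = 0
        for i in range(len(ped)):
            if fa[i] < 0:
                alleles[i, 0] = label
                alleles[i, 1] = label + 1
                label += 2
            else:
                pick_f = rng.integers(0, 2, n_reps)
                pick_m = rng.integers(0, 2, n_reps)
                alleles[i, 0] = alleles[fa[i]][pick_f, np.arange(n_reps)]
                alleles[i, 1] = alleles[mo[i]][pick_m, np.arange(n_reps)]
        for i, j in [(0, 4), (2, 4), (2, 3), (4, 4)]:
            draw_i = alleles[i][rng.integers(0, 2, n_reps), np.arange(n_reps)]
            draw_j = alleles[j][rng.integers(0, 2, n_reps), np.arange(n_reps)]
            mc = (draw_i == draw_j).mean()
            assert mc == pytest.approx(phi[i, j], abs=0.01)

    def test_kinship_matrix_is_psd(self):
        phi = pedigree_kinship(build_pedigree(SimConfig()))
        assert np.linalg.eigvalsh(phi).min() > -1e-10


class TestEmulateImputation:
    def test_perfect_quality_returns_genotypes(self, rng):
        g = rng.binomial(2, 0.4, (20, 50))
        panel = emulate_imputation(g, np.ones(50), seed=0)
        np.testing.assert_array_equal(panel.dosages, g)

    def test_zero_quality_returns_reference_mean(self, rng):
        g = rng.binomial(2, 0.4, (20, 5))
        ref = np.array([0.7, 0.8, 0.9, 1.0, 1.1])
        panel = emulate_imputation(g, np.zeros(5), ref_panel_mean=ref, seed=0)
        np.testing.assert_allclose(panel.dosages, np.tile(ref, (20, 1)))

    def test_squared_correlation_matches_nominal(self):
        rng = np.random.default_rng(6)
        g = rng.binomial(2, 0.3, (100_000, 1))
        panel = emulate_imputation(g, np.array([0.6]), seed=7)
        r2 = np.corrcoef(panel.dosages[:, 0], g[:, 0])[0, 1] ** 2
        assert r2 == pytest.approx(0.60, abs=0.02)

    def test_conditional_mean_follows_dosage_model(self):
        rng = np.random.default_rng(8)
        g = rng.binomial(2, 0.3, (200_000, 1))
        ref = np.array([0.5])
        panel = emulate_imputation(g, np.array([0.7]), ref_panel_mean=ref, seed=9)
        for gv in (0, 1, 2):
            cond = panel.dosages[g[:, 0] == gv, 0].mean()
            assert cond == pytest.approx(0.3 * 0.5 + 0.7 * gv, abs=0.02)

    def test_gaussian_law_available_and_bounded(self, rng):
        g = rng.binomial(2, 0.3, (500, 20))
        panel = emulate_imputation(g, np.full(20, 0.5), seed=1, noise="gaussian")
        assert panel.dosages.min() >= 0 and panel.dosages.max() <= 2

    def test_reestimated_rsq_tracks_nominal(self, rng):
        g = rng.binomial(2, 0.4, (2000, 10))
        panel = emulate_imputation(g, np.full(10, 0.7), seed=2,
                                   reestimate_rsq=True)
        np.testing.assert_allclose(panel.rsq, 0.7, atol=0.05)


class TestVariantFilters:
    def test_low_rsq_removed_at_default_thresholds(self, rng):
        panel = random_panel(rng, n=20, m=3, rsq=np.array([0.4, 0.5, 0.9]))
        out = apply_variant_filters(panel, maf_min=0.0, rsq_min=0.5)
        assert out.n_snps == 2  # boundary 0.5 retained, 0.4 removed

    def test_maf_boundary_is_inclusive(self):
        from dosagekin.io_formats import DosagePanel
        from conftest import make_snp_ids

        d = np.zeros((50, 2))
        d[:4, 0] = 1.0  # p = 0.04
        d[:5, 1] = 1.0  # p = 0.05
        panel = DosagePanel([f"s{i}" for i in range(50)], make_snp_ids(2), d,
                            np.ones(2))
        out = apply_variant_filters(panel, maf_min=0.05, rsq_min=0.0)
        assert [s.pos for s in out.snp_ids] == [2]

    def test_zero_thresholds_are_identity(self, rng):
        panel = random_panel(rng, n=10, m=30, rsq=rng.uniform(0, 1, 30))
        out = apply_variant_filters(panel, maf_min=0.0, rsq_min=0.0)
        assert out.n_snps == 30


class TestDeterminismAndCoverage:
    def test_same_seed_reproduces_bitwise(self):
        cfg = SimConfig(n_snps=500)
        t1, p1 = simulate_dataset(cfg, seed=11)
        t2, p2 = simulate_dataset(cfg, seed=11)
        np.testing.assert_array_equal(t1.genotypes, t2.genotypes)
        np.testing.assert_array_equal(p1.dosages, p2.dosages)
        np.testing.assert_array_equal(p1.rsq, p2.rsq)

    def test_different_seed_differs(self):
        cfg = SimConfig(n_snps=500)
        _, p1 = simulate_dataset(cfg, seed=11)
        _, p2 = simulate_dataset(cfg, seed=12)
        assert (p1.dosages != p2.dosages).any()

    def test_independent_site_coverage_multiplies_for_pairs(self, rng):
        """10% per-individual site coverage leaves ~1% of sites jointly
        observed for a pair — the motivating arithmetic for sparse data."""
        panel = random_panel(rng, n=30, m=20_000)
        observed = rng.random(panel.dosages.shape) < 0.10
        panel.dosages[~observed] = np.nan
        res = gcta_estimator(panel.dosages)
        joint = res.n_snps[np.triu_indices(30, k=1)] / panel.n_snps
        assert joint.mean() == pytest.approx(0.01, abs=0.002)


def test_dosage_calibration_across_rsq_and_maf_grid():
    """corr^2(G~, G) stays within 0.03 of nominal over the r2 x MAF grid."""
    rng = np.random.default_rng(13)
    for r2 in [0.3, 0.5, 0.7, 0.9, 1.0]:
        for maf in [0.05, 0.1, 0.25, 0.4]:
            g = rng.binomial(2, maf, (30_000, 1))
            panel = emulate_imputation(g, np.array([r2]), seed=rng)
            if r2 == 1.0:
                np.testing.assert_array_equal(panel.dosages, g)
                continue
            emp = np.corrcoef(panel.dosages[:, 0], g[:, 0])[0, 1] ** 2
            assert emp == pytest.approx(r2, abs=0.03), (r2, maf)
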