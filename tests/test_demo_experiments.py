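import math

import numpy as np
import pytest

from gsped.demo_experiments import (CategoryProbs, ExperimentConfig,
                                    PanelConfig, backcross_probs,
                                    category_gsp, category_probs, cross_probs,
                                    gsp_for_admixture, linkage_experiment,
                                    run_rispi_experiment,
                                    sim_admixed_with_replacement,
                                    sim_reference_panels,
                                    sim_unlinked_admixture,
                                    sim_unlinked_hybrids, supervised_q_mle,
                                    supervised_q_mle_many)
from gsped.genetic_map import GenomeSpec
from gsped.gsp import validate_gsp
from gsped.permute import GenotypeMatrix

from .conftest import make_marker_map


def fixed_freq_panels(L=20, N=6):
    """Panels fixed for alternate alleles ("1" in A, "2" in B)."""
    mm = make_marker_map((L,), spacing_bp=1000)
    a = GenotypeMatrix(np.full((N, 2 * L), "1"), np.array([f"a{i}" for i in range(N)]),
                       np.full(N, "A"), mm)
    b = GenotypeMatrix(np.full((N, 2 * L), "2"), np.array([f"b{i}" for i in range(N)]),
                       np.full(N, "B"), mm)
    return a, b


class TestCategoryProbs:
    def test_builtin_triplets(self):
        assert category_probs("F1").triplet == (0.0, 1.0, 0.0)
        assert category_probs("F2").triplet == (0.25, 0.5, 0.25)
        assert category_probs("BC1").triplet == (0.5, 0.5, 0.0)
        assert category_probs("BC2").triplet == (0.75, 0.25, 0.0)
        assert backcross_probs(3).triplet == (0.875, 0.125, 0.0)

    def test_compound_cross_from_gamete_probabilities(self):
        # BC1 gamete carries population-a ancestry w.p. 3/4; BC2 gamete w.p. 7/8
        cat = category_probs("BC1xBC2")
        assert cat.triplet == pytest.approx((21 / 32, 10 / 32, 1 / 32))
        assert cross_probs("x", 0.75, 0.875).triplet == cat.triplet

    def test_invalid_triplet_rejected(self):
        with pytest.raises(ValueError):
            CategoryProbs("bad", 0.9, 0.3, -0.2)

    def test_category_gsps_validate_and_match_expected_q(self, toy_genome):
        for name in ("F1", "F2", "BC1", "BC2", "BC3", "BC1xBC2"):
            gsp = category_gsp(name)
            assert validate_gsp(gsp).valid, name


class TestReferencePanels:
    def test_beta_mean_matches_shape_parameters(self):
        cfg = PanelConfig(L=20000, N=2)
        _, _, freqs = sim_reference_panels(cfg, rng=np.random.default_rng(0))
        # Beta(1,8) mean = 1/9; SE = sd/sqrt(L)
        se = freqs.std() / math.sqrt(len(freqs))
        assert abs(freqs.mean() - 1 / 9) < 4 * se

    def test_panels_follow_hwe_at_large_n(self):
        cfg = PanelConfig(L=5, N=4000)
        pa, _, freqs = sim_reference_panels(cfg, rng=np.random.default_rng(1))
        hets = (pa.alleles[:, 0::2] != pa.alleles[:, 1::2]).mean(axis=0)
        expect = 2 * freqs * (1 - freqs)
        se = np.sqrt(expect * (1 - expect) / cfg.N)
        assert (np.abs(hets - expect) < 4 * se + 1e-9).all()

    def test_same_seed_gives_identical_panels(self):
        cfg = PanelConfig(L=50, N=5)
        a1, b1, f1 = sim_reference_panels(cfg, rng=np.random.default_rng(7))
        a2, b2, f2 = sim_reference_panels(cfg, rng=np.random.default_rng(7))
        assert (a1.alleles == a2.alleles).all()
        assert (b1.alleles == b2.alleles).all()
        assert (f1 == f2).all()

    def test_loci_live_on_the_supplied_genome(self):
        g = GenomeSpec(("X1", "X2"), (1000, 3000))
        cfg = PanelConfig(L=30, N=2)
        pa, _, _ = sim_reference_panels(cfg, genome=g, rng=np.random.default_rng(2))
        assert set(pa.markers.chroms) <= {"X1", "X2"}


class TestNaiveSimulators:
    def test_qa_one_draws_only_from_panel_a(self):
        a, b = fixed_freq_panels()
        out = sim_admixed_with_replacement(a, b, 1.0, 5, np.random.default_rng(0))
        assert (out.alleles == "1").all()

    def test_qa_half_realised_fraction_is_binomial(self):
        a, b = fixed_freq_panels(L=2000)
        out = sim_admixed_with_replacement(a, b, 0.5, 1, np.random.default_rng(1))
        frac = (out.alleles == "1").mean()
        assert abs(frac - 0.5) < 4 * math.sqrt(0.25 / (2 * 2000))

    def test_n_zero_gives_empty_matrix(self):
        a, b = fixed_freq_panels()
        out = sim_admixed_with_replacement(a, b, 0.3, 0, np.random.default_rng(2))
        assert out.n_ind == 0

    def test_invalid_q_rejected(self):
        a, b = fixed_freq_panels()
        with pytest.raises(ValueError):
            sim_admixed_with_replacement(a, b, 1.5, 1, np.random.default_rng(0))

    def test_unlinked_f1_is_heterozygous_with_exact_half_admixture(self):
        a, b = fixed_freq_panels()
        geno, q = sim_unlinked_hybrids(a, b, category_probs("F1"), 8,
                                       np.random.default_rng(3))
        assert (q == 0.5).all()
        assert (np.sort(geno.alleles.reshape(geno.n_ind, -1, 2), axis=2)
                == np.array(["1", "2"])).all()

    def test_unlinked_bc2_never_lacks_population_a_ancestry(self):
        a, b = fixed_freq_panels(L=500)
        geno, q = sim_unlinked_hybrids(a, b, category_probs("BC2"), 20,
                                       np.random.default_rng(4))
        both_b = (geno.alleles[:, 0::2] == "2") & (geno.alleles[:, 1::2] == "2")
        assert not both_b.any()
        assert (q >= 0.75).all()

    def test_unlinked_admixture_variance_scales_inversely_with_loci(self):
        rng = np.random.default_rng(5)
        cat = category_probs("BC2")
        v1 = sim_unlinked_admixture(cat, 1000, 4000, rng).var()
        v2 = sim_unlinked_admixture(cat, 10000, 4000, rng).var()
        assert v1 / v2 == pytest.approx(10.0, rel=0.25)

    def test_multinomial_shortcut_matches_genotype_level_distribution(self):
        a, b = fixed_freq_panels(L=400)
        rng = np.random.default_rng(6)
        cat = category_probs("F2")
        _, q_full = sim_unlinked_hybrids(a, b, cat, 600, rng)
        q_fast = sim_unlinked_admixture(cat, 400, 600, rng)
        assert abs(q_full.mean() - q_fast.mean()) < 4 * q_full.std() / math.sqrt(600) * 1.5
        assert q_full.var() == pytest.approx(q_fast.var(), rel=0.3)


class TestSupervisedMle:
    def test_boundary_mle_for_unambiguous_individual(self):
        row = np.full(200, "1")
        est = supervised_q_mle(row, np.full(100, 0.99), np.full(100, 0.01),
                               n_ref_a=50, n_ref_b=50)
        assert est.q_hat == pytest.approx(1.0, abs=1e-3)
        assert np.isfinite(est.log_lik)

    def test_flat_likelihood_ties_to_half(self):
        row = np.array(["1", "2"] * 50)
        f = np.full(50, 0.3)
        est = supervised_q_mle(row, f, f, n_ref_a=50, n_ref_b=50)
        assert est.q_hat == 0.5
        assert est.iterations == 0

    def test_missing_only_individual_warns_and_returns_half(self):
        row = np.full(20, "0")
        with pytest.warns(UserWarning, match="zero informative"):
            est = supervised_q_mle(row, np.full(10, 0.4), np.full(10, 0.6),
                                   n_ref_a=10, n_ref_b=10)
        assert est.q_hat == 0.5

    def test_parameter_recovery_on_diverged_panels(self):
        rng = np.random.default_rng(8)
        L, q_true = 1000, 0.25
        fa = np.full(L, 0.9)
        fb = np.full(L, 0.1)
        origin = rng.random((30, 2 * L)) < q_true
        p = np.where(origin, 0.9, 0.1)
        alleles = np.where(rng.random((30, 2 * L)) < p, "1", "2")
        geno = GenotypeMatrix(alleles, np.array([f"i{k}" for k in range(30)]),
                              np.full(30, "?"), None)
        ests = supervised_q_mle_many(geno, fa, fb, n_ref_a=500, n_ref_b=500)
        qh = np.array([e.q_hat for e in ests])
        assert abs(qh.mean() - q_true) < 4 * qh.std() / math.sqrt(len(qh)) + 0.01

    def test_estimator_sharpens_with_more_loci(self):
        rng = np.random.default_rng(9)
        errs = []
        for L in (100, 1000, 10000):
            fa, fb = np.full(L, 0.8), np.full(L, 0.2)
            origin = rng.random((20, 2 * L)) < 0.25
            p = np.where(origin, 0.8, 0.2)
            alleles = np.where(rng.random((20, 2 * L)) < p, "1", "2")
            geno = GenotypeMatrix(alleles, np.array([f"i{k}" for k in range(20)]),
                                  np.full(20, "?"), None)
            qh = np.array([
                e.q_hat for e in supervised_q_mle_many(geno, fa, fb, 500, 500)
            ])
            errs.append(np.abs(qh - 0.25).mean())
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.01


class TestExperiments:
    def test_gsp_for_admixture_realises_the_default_grid_exactly(self):
        for q in (0.0, 1 / 8, 1 / 4, 3 / 8, 1 / 2, 5 / 8, 3 / 4, 7 / 8, 1.0):
            gsp, realised = gsp_for_admixture(q)
            assert realised == q
            assert validate_gsp(gsp).valid
            # conservation fixes the mean admixture to the founder fraction
            pops = [p for f in gsp.founders.values() for p in f.hap_pops]
            assert pops.count("A") / len(pops) == pytest.approx(q)

    def test_off_grid_q_falls_back_to_nearest(self):
        _, realised = gsp_for_admixture(0.3)
        assert realised == 0.25

    def test_rispi_table_shape_and_determinism(self):
        cfg = ExperimentConfig(L_values=(100,), N_values=(25,), n=3, R=1,
                               q_grid=(0.0, 0.5, 1.0))
        t1 = run_rispi_experiment(cfg, "with_replacement", seed=5)
        t2 = run_rispi_experiment(cfg, "with_replacement", seed=5)
        assert t1.equals(t2)
        assert len(t1) == 3 * 3
        assert set(t1.columns) >= {"L", "N", "n", "qA", "rep", "id", "q_hat"}
        g1 = run_rispi_experiment(cfg, "gsp", seed=5)
        g2 = run_rispi_experiment(cfg, "gsp", seed=5)
        assert g1.equals(g2)
        assert (g1["realised_q"] == g1["qA"]).all()

    def test_linkage_experiment_table(self, toy_genome, toy_recmap):
        t = linkage_experiment(("F1", "BC1"), (100, 1000), n=40,
                               rec_map=toy_recmap, genome=toy_genome, seed=3)
        assert set(t["source"]) == {"unlinked", "linked"}
        f1_linked = t[(t.category == "F1") & (t.source == "linked")].iloc[0]
        assert f1_linked["mean"] == pytest.approx(0.5, abs=1e-12)
        assert f1_linked["sd"] == pytest.approx(0.0, abs=1e-12)
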