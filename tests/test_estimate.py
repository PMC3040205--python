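import warnings

import numpy as np
import pytest

from oracles import grid_search_loglik, product_loglikelihood
from trimix import (
    AlleleFrequencyPanel,
    GenotypeMatrix,
    MISSING,
    SimulationConfig,
    em_step,
    estimate_cohort,
    estimate_individual,
    loglikelihood,
    simulate_cohort,
    simulate_reference_panel,
)
from trimix.estimate import bootstrap_se


def _uniform_panel(p: float, n_loci: int) -> AlleleFrequencyPanel:
    return AlleleFrequencyPanel(
        pop_ids=["european", "african", "amerindian"],
        locus_ids=[f"L{i}" for i in range(n_loci)],
        freqs=np.full((3, n_loci), p),
    )


class TestLoglikelihood:
    def test_closed_form_heterozygotes(self):
        # m = 0.5 everywhere, all heterozygous: P(g=1) = 0.5 per locus
        panel = _uniform_panel(0.5, 4)
        ll = loglikelihood((1 / 3, 1 / 3, 1 / 3), [1, 1, 1, 1], panel)
        assert ll == pytest.approx(4 * np.log(0.5), abs=1e-12)

    def test_all_missing_raises(self, small_panel):
        with pytest.raises(ValueError, match="no informative loci"):
            loglikelihood((1 / 3, 1 / 3, 1 / 3), [MISSING] * 5, small_panel)

    def test_missing_loci_skipped(self, small_panel):
        full = loglikelihood((0.2, 0.3, 0.5), [1, 0, 2, 1, 0], small_panel)
        partial = loglikelihood((0.2, 0.3, 0.5), [1, 0, MISSING, 1, MISSING], small_panel)
        sub = small_panel.align_loci(["L1", "L2", "L4"])
        assert partial == pytest.approx(loglikelihood((0.2, 0.3, 0.5), [1, 0, 1], sub), abs=1e-12)
        assert partial != pytest.approx(full)

    def test_off_simplex_rejected(self, small_panel):
        with pytest.raises(ValueError, match="simplex"):
            loglikelihood((0.5, 0.5, 0.5), [1, 1, 1, 1, 1], small_panel)

    def test_matches_product_oracle(self, small_panel, rng):
        for _ in range(20):
            q = rng.dirichlet((1, 1, 1))
            g = rng.integers(0, 3, size=5)
            expected = product_loglikelihood(q, g, small_panel.freqs)
            assert loglikelihood(q, g, small_panel) == pytest.approx(expected, abs=1e-12)


class TestEMStep:
    def test_fixed_point_at_unconstrained_optimum(self):
        # one locus, g = 1: optimum at m = 0.5; q chosen so q.p = 0.5
        panel = AlleleFrequencyPanel(
            ["european", "african", "amerindian"], ["L1"], np.array([[0.2], [0.5], [0.8]])
        )
        q = np.array([0.25, 0.5, 0.25])
        np.testing.assert_allclose(em_step(q, [1], panel), q, atol=1e-9)

    def test_output_on_simplex(self, small_panel, rng):
        for _ in range(25):
            q = rng.dirichlet((2, 2, 2))
            g = rng.integers(0, 3, size=5)
            out = em_step(q, g, small_panel)
            assert abs(out.sum() - 1.0) < 1e-12
            assert (out >= 0).all()

    def test_monotone_loglikelihood(self, small_panel, rng):
        for _ in range(10):
            q = rng.dirichlet((1, 1, 1)) * 0.99 + 0.01 / 3
            g = rng.integers(0, 3, size=5)
            ll = loglikelihood(q, g, small_panel)
            for _ in range(50):
                q = em_step(q, g, small_panel)
                ll_new = loglikelihood(q, g, small_panel)
                assert ll_new >= ll - 1e-10
                ll = ll_new

    def test_random_starts_reach_grid_optimum(self, rng):
        # concave likelihood: every start must reach the same optimum
        p = rng.uniform(0.05, 0.95, size=(3, 10))
        panel = AlleleFrequencyPanel(
            ["european", "african", "amerindian"], [f"L{i}" for i in range(10)], p
        )
        q_true = rng.dirichlet((1, 1, 1))
        g = rng.binomial(2, q_true @ p)
        _, grid_ll = grid_search_loglik(g, p)
        for _ in range(100):
            q = rng.dirichlet((1, 1, 1)) * 0.99 + 0.01 / 3
            ll = loglikelihood(q, g, panel)
            for _ in range(50_000):
                q = em_step(q, g, panel)
                ll_new = loglikelihood(q, g, panel)
                if abs(ll_new - ll) < 1e-13:
                    break
                ll = ll_new
            assert ll_new >= grid_ll - 1e-6


class TestEstimateIndividual:
    def test_perfect_markers_recover_source(self):
        cfg = SimulationConfig(
            fst=0.15,
            n_loci=40,
            dirichlet_params={},
            cohort_sizes={},
            seed=4,
            fixed_differences=True,
        )
        panel = simulate_reference_panel(cfg)
        rng = np.random.default_rng(7)
        g = rng.binomial(2, panel.freqs[0])  # pure source-1 individual
        av = estimate_individual(g, panel)
        assert av.q[0] >= 0.99

    def test_symmetric_panel_flagged_and_uniform(self):
        panel = _uniform_panel(0.4, 20)
        g = np.random.default_rng(0).binomial(2, np.full(20, 0.4))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            av = estimate_individual(g, panel)
        assert not av.identifiable
        np.testing.assert_allclose(av.q, [1 / 3] * 3, atol=1e-9)

    def test_matches_grid_oracle_accuracy(self):
        cfg = SimulationConfig(
            fst=0.15,
            n_loci=40,
            dirichlet_params={("R", "Brown"): (3.0, 3.0, 3.0)},
            cohort_sizes={("R", "Brown"): 200},
            seed=8,
        )
        panel = simulate_reference_panel(cfg)
        cohort = simulate_cohort(panel, cfg)
        est = np.array(
            [estimate_individual(row, panel).q for row in cohort.genotypes.values]
        )
        grid = np.array(
            [grid_search_loglik(row, panel.freqs)[0] for row in cohort.genotypes.values]
        )
        rmse_est = np.sqrt(np.mean((est - cohort.true_ancestry) ** 2))
        rmse_grid = np.sqrt(np.mean((grid - cohort.true_ancestry) ** 2))
        assert rmse_est <= rmse_grid + 0.005

    def test_n_used_counts_nonmissing(self, small_panel):
        g = np.array([1, MISSING, 0, 2, MISSING])
        av = estimate_individual(g, small_panel)
        assert av.n_used == 3

    def test_label_equivariance(self, small_panel, rng):
        g = rng.integers(0, 3, size=5)
        perm = [2, 0, 1]
        permuted = AlleleFrequencyPanel(
            [small_panel.pop_ids[k] for k in perm],
            small_panel.locus_ids,
            small_panel.freqs[perm],
        )
        q1 = estimate_individual(g, small_panel).q
        q2 = estimate_individual(g, permuted).q
        np.testing.assert_allclose([q1[k] for k in perm], q2, atol=1e-6)


class TestEstimateCohort:
    def test_empty_matrix(self, small_panel):
        empty = GenotypeMatrix(
            individual_ids=[], locus_ids=small_panel.locus_ids, values=np.empty((0, 5), dtype=int)
        )
        assert estimate_cohort(empty, small_panel) == []

    def test_matches_rowwise_loop(self, sim_cohort):
        panel, cohort = sim_cohort
        batch = estimate_cohort(cohort.genotypes, panel)
        for i, av in enumerate(batch):
            single = estimate_individual(cohort.genotypes.values[i], panel)
            assert av.q == single.q
            assert av.loglik == single.loglik

    def test_permutation_equivariance(self, sim_cohort, rng):
        panel, cohort = sim_cohort
        order = rng.permutation(cohort.genotypes.n_individuals)
        shuffled = GenotypeMatrix(
            individual_ids=[cohort.genotypes.individual_ids[i] for i in order],
            locus_ids=cohort.genotypes.locus_ids,
            values=cohort.genotypes.values[order],
            regions=[cohort.genotypes.regions[i] for i in order],
            colors=[cohort.genotypes.colors[i] for i in order],
        )
        base = estimate_cohort(cohort.genotypes, panel)
        perm = estimate_cohort(shuffled, panel)
        for i, j in enumerate(order):
            assert perm[i].q == base[j].q

    def test_failed_rows_flagged_not_fatal(self, small_panel):
        values = np.array([[1, 0, 2, 1, 0], [MISSING] * 5])
        gm = GenotypeMatrix(
            individual_ids=["ok", "allmissing"], locus_ids=small_panel.locus_ids, values=values
        )
        out = estimate_cohort(gm, small_panel)
        assert out[0].error is None
        assert out[1].error is not None and "no informative loci" in out[1].error

    def test_aligns_loci_by_id_not_position(self, small_panel, rng):
        g = rng.integers(0, 3, size=5)
        gm = GenotypeMatrix(
            individual_ids=["a"], locus_ids=["L5", "L4", "L3", "L2", "L1"], values=g[None, ::-1]
        )
        gm.values = gm.values.copy()
        # reversed locus order in the matrix must give the same estimate
        direct = estimate_individual(g, small_panel)
        via_cohort = estimate_cohort(gm, small_panel)[0]
        np.testing.assert_allclose(via_cohort.q, direct.q, atol=1e-6)


def test_bootstrap_se_positive_and_reproducible(small_panel, rng):
    g = rng.integers(0, 3, size=5)
    av = estimate_individual(g, small_panel)
    se1 = bootstrap_se(g, small_panel, av.q, n_reps=30, seed=5)
    se2 = bootstrap_se(g, small_panel, av.q, n_reps=30, seed=5)
    np.testing.assert_array_equal(se1, se2)
    assert (se1 >= 0).all()
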