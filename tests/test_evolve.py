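"""NSGA-II optimizer tests against analytic oracles, plus stage-wise
evaluation filters on miniature brain networks."""

import numpy as np
import pytest

from slowbrain.evolve import (
    GENE_BOUNDS,
    GENE_NAMES,
    Individual,
    _truncate,
    crowding_distance,
    fast_non_dominated_sort,
    nsga2_evolve,
    polynomial_mutation,
    sbx_crossover,
    stagewise_evaluate,
)


def _toy_eval(genome, _index):
    """Biobjective benchmark min(x^2, (x-2)^2): Pareto set is x in [0, 2]."""
    x = genome[0]
    return (x**2, (x - 2.0) ** 2)


TOY_BOUNDS = np.array([[-4.0, 6.0]])


class TestOptimizer:
    def test_front_recovers_analytic_pareto_set(self):
        pop = nsga2_evolve(_toy_eval, TOY_BOUNDS, n_init=40, n_pop=20,
                           n_gen=30, seed=0)
        front = [ind for ind in pop if ind.rank == 0]
        assert len(front) >= 10
        xs = np.array([ind.genome[0] for ind in front])
        assert np.all(xs >= -0.05) and np.all(xs <= 2.05)
        # the front should spread over the Pareto set, not collapse
        assert xs.max() - xs.min() > 1.0

    def test_rank_zero_is_mutually_non_dominated(self):
        pop = nsga2_evolve(_toy_eval, TOY_BOUNDS, n_init=30, n_pop=15,
                           n_gen=5, seed=1)
        F = np.array([ind.objectives for ind in pop if ind.rank == 0])
        for a in F:
            for b in F:
                assert not (np.all(a <= b) and np.any(a < b)) or np.array_equal(a, b)

    def test_seeded_run_is_reproducible(self):
        f1 = nsga2_evolve(_toy_eval, TOY_BOUNDS, n_init=30, n_pop=15,
                          n_gen=10, seed=7)
        f2 = nsga2_evolve(_toy_eval, TOY_BOUNDS, n_init=30, n_pop=15,
                          n_gen=10, seed=7)
        assert np.array_equal(
            np.array([i.genome for i in f1]), np.array([i.genome for i in f2])
        )

    def test_archive_hypervolume_never_decreases(self):
        ref = np.array([40.0, 40.0])
        hvs = []

        def _hv_2d(F):
            # rectangle-sweep hypervolume for a 2-D minimization front
            F = F[np.argsort(F[:, 0])]
            hv, prev_y = 0.0, ref[1]
            for x, y in F:
                if y < prev_y:
                    hv += (ref[0] - x) * (prev_y - y)
                    prev_y = y
            return hv

        def _cb(gen, pop, archive):
            F = np.array([i.objectives for i in archive])
            hvs.append(_hv_2d(F))

        nsga2_evolve(_toy_eval, TOY_BOUNDS, n_init=30, n_pop=15, n_gen=15,
                     seed=3, callback=_cb)
        assert len(hvs) == 15
        assert all(b >= a - 1e-12 for a, b in zip(hvs, hvs[1:]))

    def test_elitism_keeps_rank_zero_under_truncation(self):
        rng = np.random.default_rng(0)
        pop = [Individual(genome=np.array([i]), objectives=tuple(v))
               for i, v in enumerate(rng.uniform(0, 1, size=(30, 2)))]
        F = np.array([i.objectives for i in pop])
        rank0 = set(map(tuple, F[fast_non_dominated_sort(F)[0]]))
        survivors = _truncate(pop, 12)
        kept = set(ind.objectives for ind in survivors)
        if len(rank0) <= 12:
            assert rank0 <= kept

    def test_operators_respect_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            p1 = rng.uniform(GENE_BOUNDS[:, 0], GENE_BOUNDS[:, 1])
            p2 = rng.uniform(GENE_BOUNDS[:, 0], GENE_BOUNDS[:, 1])
            c1, c2 = sbx_crossover(p1, p2, GENE_BOUNDS, rng)
            m = polynomial_mutation(c1, GENE_BOUNDS, rng)
            for g in (c1, c2, m):
                assert np.all(g >= GENE_BOUNDS[:, 0])
                assert np.all(g <= GENE_BOUNDS[:, 1])

    def test_crowding_extremes_are_infinite(self):
        F = np.array([[0.0, 3.0], [1.0, 1.0], [3.0, 0.0]])
        d = crowding_distance(F)
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert np.isfinite(d[1])

    def test_all_invalid_initial_population_raises(self):
        with pytest.raises(RuntimeError):
            nsga2_evolve(lambda g, i: None, TOY_BOUNDS, n_init=5, n_pop=4,
                         n_gen=2, seed=0)


class TestStagewise:
    def test_silent_dynamics_rejected_at_stage_one(self, table):
        """A genome whose network never exceeds 10 Hz anywhere is marked
        invalid by the screening stage."""
        from slowbrain import synthetic_connectome
        from slowbrain.evolve import FitTargets

        conn = synthetic_connectome(10, seed=2)
        genes = dict(mu_E_ext=0.0, mu_I_ext=3.5, b=0.0, tau_A=1000.0,
                     K_gl=100.0, sigma_ou=0.05)
        fv = stagewise_evaluate(genes, conn, table, FitTargets(), seed=0,
                                duration=40_000.0)
        assert not fv.valid

    def test_tonic_firing_passes_filters_and_scores(self, table):
        from slowbrain import synthetic_connectome, generate_fixtures

        fx = generate_fixtures(N=10, K=2, seed=3, duration_s=200.0)
        # adaptation below the small network's critical value keeps the
        # median rate inside the tonic [1, 15] Hz screening band
        genes = dict(mu_E_ext=3.3, mu_I_ext=3.7, b=2.4, tau_A=4765.0,
                     K_gl=265.0, sigma_ou=0.37)
        fv = stagewise_evaluate(genes, fx.connectome, table, fx.targets(),
                                mode="fmri_eeg_up2down", seed=1,
                                duration=100_000.0)
        assert fv.valid
        assert -1.0 <= fv.fc_corr <= 1.0
        assert 0.0 <= fv.fcd_ks <= 1.0
        assert -1.0 <= fv.spec_corr <= 1.0

    def test_excessive_up_state_rejected_in_up2down_mode(self, table):
        """Median rate above 15 Hz violates the tonic-sleep screening
        filter in up-to-down mode but not in fmri_only mode's screen."""
        from slowbrain import synthetic_connectome
        from slowbrain.evolve import FitTargets

        conn = synthetic_connectome(10, seed=2)
        genes = dict(mu_E_ext=4.0, mu_I_ext=1.0, b=0.0, tau_A=1000.0,
                     K_gl=300.0, sigma_ou=0.05)
        fv = stagewise_evaluate(genes, conn, table, FitTargets(),
                                mode="fmri_eeg_up2down", seed=2,
                                duration=40_000.0)
        assert not fv.valid

    def test_unknown_mode_rejected(self, table):
        from slowbrain import synthetic_connectome
        from slowbrain.evolve import FitTargets

        with pytest.raises(ValueError):
            stagewise_evaluate({g: 1.0 for g in GENE_NAMES},
                               synthetic_connectome(10, seed=0), table,
                               FitTargets(), mode="bogus")


def test_mini_evolution_yields_valid_front(table):
    """A desk-scale two-objective (fMRI-only) evolution on a small synthetic
    network produces a Pareto front with at least one valid individual."""
    from slowbrain import generate_fixtures
    from slowbrain.evolve import evolve_brain_model

    fx = generate_fixtures(N=10, K=2, seed=6, duration_s=200.0)
    pop = evolve_brain_model(
        fx.connectome, table, fx.targets(), mode="fmri_only",
        n_init=6, n_pop=4, n_gen=2, seed=5, duration=100_000.0,
        rec_dt=10.0,
    )
    front = [ind for ind in pop if ind.rank == 0 and ind.fitness.valid]
    assert len(front) >= 1
    for ind in front:
        assert np.all(ind.genome >= GENE_BOUNDS[:, 0])
        assert np.all(ind.genome <= GENE_BOUNDS[:, 1])
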