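"""Mutation-selection mechanics: the mutation operator, one-generation
dynamics on a toy objective, and short seeded runs of the real experiment."""

import numpy as np
import pytest

from segevo.evolution import (
    EvolutionConfig, MutationSpec, Individual, mutate, step_generation,
    evolve_fly_to_mosquito, optimize_stripe_widths, make_evaluator,
)
from segevo.fitness import FitnessReport
from segevo.fly import make_targets
from segevo.network import GAP_MODULES
from segevo.phenotype import call_stripes, module_is_lost
from segevo.solver import solve_profiles


def _desk_config(**kw):
    defaults = dict(population_size=8, generation_cap=30, snapshot_every=10,
                    stop_total=0.5,
                    mutation=MutationSpec(step_sigma=0.25, p_elimination=0.05))
    defaults.update(kw)
    return EvolutionConfig(**defaults)


class TestMutate:
    def test_zero_sigma_no_elimination_leaves_parameters_unchanged(self, fly, rng):
        spec = MutationSpec(step_sigma=0.0, p_elimination=0.0)
        child = mutate(fly, spec, rng)
        assert np.array_equal(child.param_vector(), fly.param_vector())

    def test_only_evolvable_parameters_ever_change(self, fly):
        """10,000 mutations: frozen parameters stay bit-identical and values
        respect their clamp ranges."""
        rng = np.random.default_rng(7)
        spec = MutationSpec(step_sigma=0.5, p_elimination=0.1)
        reg = fly.registry()
        frozen = ~reg.evolvable
        base = fly.param_vector()
        net = fly
        for _ in range(10_000):
            net = mutate(net, spec, rng)
        vec = net.param_vector()
        assert np.array_equal(vec[frozen], base[frozen])
        assert np.all(vec >= reg.lo) and np.all(vec <= reg.hi)
        # maternal gradients are frozen too
        assert np.array_equal(net.maternal.as_array(), fly.maternal.as_array())

    def test_elimination_move_silences_module(self, fly):
        rng = np.random.default_rng(3)
        spec = MutationSpec(step_sigma=0.2, p_elimination=1.0)
        child = mutate(fly, spec, rng)
        eliminated = [m for m in child.solved_modules if child.kernels[m].eliminated]
        assert len(eliminated) == 1
        profiles, _ = solve_profiles(child)
        assert module_is_lost(profiles[eliminated[0]], child.loss_threshold)

    def test_elimination_is_reversible(self, fly):
        rng = np.random.default_rng(3)
        spec = MutationSpec(step_sigma=0.2, p_elimination=1.0, resurrection_value=0.3)
        child = mutate(fly, spec, rng)
        name = next(m for m in child.solved_modules if child.kernels[m].eliminated)
        # force the same module again: toggle back
        for _ in range(200):
            child2 = mutate(child, spec, np.random.default_rng(rng.integers(2**31)))
            if not child2.kernels[name].eliminated and child2.kernels[name].max_rate > 0:
                assert child2.kernels[name].max_rate == 0.3
                break
        else:
            pytest.fail("resurrection move never hit the eliminated module")


class ToyIndividual:
    """Quadratic objective over a single parameter, via the real machinery."""


def _toy_evaluate(network, gap=None):
    v = network.kernels["eve2"].get_param("max_rate")
    total = (v - 0.123) ** 2
    return FitnessReport(total, 0.0, 0.0, 0.0, total, eve_count=7), None


class TestStepGeneration:
    def test_population_size_preserved_and_even_required(self, fly, rng):
        spec = MutationSpec(step_sigma=0.1, p_elimination=0.0)
        pop = [Individual(fly, _toy_evaluate(fly)[0]) for _ in range(6)]
        out = step_generation(pop, _toy_evaluate, spec, rng)
        assert len(out) == 6
        with pytest.raises(ValueError):
            step_generation(pop[:3], _toy_evaluate, spec, rng)

    def test_zero_step_mutation_leaves_population_unchanged(self, fly, rng):
        spec = MutationSpec(step_sigma=0.0, p_elimination=0.0)
        pop = [Individual(fly, _toy_evaluate(fly)[0]) for _ in range(4)]
        out = step_generation(pop, _toy_evaluate, spec, rng, neutral_band=0.0)
        assert [ind.report.total for ind in out] == [ind.report.total for ind in pop]

    def test_toy_quadratic_objective_descends(self, fly):
        """50 generations, population 10: best fitness non-increasing and
        strictly improved at least once."""
        rng = np.random.default_rng(11)
        spec = MutationSpec(step_sigma=0.2, p_elimination=0.0)
        pop = [Individual(fly, _toy_evaluate(fly)[0]) for _ in range(10)]
        best = [min(ind.report.total for ind in pop)]
        for _ in range(50):
            pop = step_generation(pop, _toy_evaluate, spec, rng)
            best.append(min(ind.report.total for ind in pop))
        diffs = np.diff(best)
        assert np.all(diffs <= 1e-12)
        assert np.any(diffs < 0)


class TestExperimentRuns:
    def test_short_run_invariants(self):
        """A short seeded fly-to-mosquito run: best fitness monotone within
        the neutral band, stripe-count constraint maintained by every
        member of every generation, population bookkeeping sane."""
        cfg = _desk_config()
        traj = evolve_fly_to_mosquito(cfg, seed=5)
        totals = traj.best_totals
        assert np.all(np.diff(totals) <= cfg.neutral_band + 1e-12)
        assert traj.min_eve_counts.min() >= 7
        assert traj.records[0].best_total > 0

    def test_bit_exact_reproducibility(self):
        cfg = _desk_config(generation_cap=15)
        a = evolve_fly_to_mosquito(cfg, seed=9)
        b = evolve_fly_to_mosquito(cfg, seed=9)
        assert np.array_equal(a.best_totals, b.best_totals)
        assert np.array_equal(a.final_network.param_vector(),
                              b.final_network.param_vector())
        assert a.config_hash == b.config_hash

    def test_different_seeds_diverge(self):
        cfg = _desk_config(generation_cap=15)
        a = evolve_fly_to_mosquito(cfg, seed=1)
        b = evolve_fly_to_mosquito(cfg, seed=2)
        assert not np.array_equal(a.best_totals, b.best_totals)

    def test_snapshots_reevaluate_to_recorded_fitness(self):
        from segevo.io import network_from_dict
        from segevo.fitness import evaluate_fitness
        cfg = _desk_config(generation_cap=20, snapshot_every=10)
        traj = evolve_fly_to_mosquito(cfg, seed=5)
        targets = make_targets()
        for gen, doc, report in traj.snapshots:
            net = network_from_dict(doc)
            again = evaluate_fitness(net, targets, cfg.fitness)
            assert again.total == pytest.approx(report["total"], abs=1e-9)


class TestReverseExperiment:
    def test_lca_to_fly_mechanics(self):
        """The reverse run starts from a forward end state, targets the fly
        gap configuration, and obeys the same invariants (monotone best
        fitness, constraint maintenance). Full re-creation of the eve 5
        stripe is a long-run outcome not asserted at this scale."""
        from segevo.evolution import evolve_lca_to_fly
        fwd = evolve_fly_to_mosquito(_desk_config(generation_cap=60), seed=3)
        cfg = _desk_config(generation_cap=40)
        back = evolve_lca_to_fly(fwd.final_network, cfg, seed=4)
        assert np.all(np.diff(back.best_totals) <= cfg.neutral_band + 1e-12)
        assert back.min_eve_counts.min() >= 7
        # the fly target is not already met at the start of the reverse run
        assert back.records[0].best_total > 0


class TestConsolidateLca:
    def test_amplitude_width_spread_never_increases(self, fly):
        """Consolidation keeps the stripe count and only ever reduces the
        spread of stripe amplitudes and widths."""
        from segevo.evolution import consolidate_lca
        from segevo.fly import make_targets
        targets = make_targets(fly=fly)
        out = consolidate_lca(fly, targets, _desk_config(), seed=3, iterations=150)

        def spread(net):
            profiles, _ = solve_profiles(net)
            ev = call_stripes(profiles["eve"], net.grid)
            amps = np.array([s.amplitude for s in ev])
            return len(ev), float(np.var(amps / amps.mean())
                                  + np.var(ev.widths / ev.widths.mean()))

        n0, s0 = spread(fly)
        n1, s1 = spread(out)
        assert n1 == n0
        assert s1 <= s0 + 1e-12


class TestOptimizeStripeWidths:
    def test_width_variance_never_increases(self, fly):
        out = optimize_stripe_widths(fly, iterations=60, seed=2)
        profiles0, _ = solve_profiles(fly)
        profiles1, _ = solve_profiles(out)
        ev0 = call_stripes(profiles0["eve"], fly.grid)
        ev1 = call_stripes(profiles1["eve"], out.grid)
        assert len(ev1) == len(ev0)
        assert np.var(ev1.widths) <= np.var(ev0.widths) + 1e-12
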