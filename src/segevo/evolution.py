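"""Mutation-selection dynamics over network parameters, and the two
headline experiments: fly to mosquito, and back from the inferred last
common ancestor (LCA) to the fly.

The algorithm mutates only numerical kernel parameters (half-saturations
and maximal rates); it never creates kernels or adds inputs, and the
maternal gradients are frozen. A rare *elimination move* toggles a module's
maximal rate to zero (enhancer loss) or, if already zero, back to a small
resurrection value — mutation rates are the same forward and backward in
time. Each generation every member is mutated; a mutant replaces its parent
if it is fitter, with module loss accepted inside a small neutral band (a
parsimony tie-break: the phenotypically silent loss of an unused module is
the very event the experiments are about, and a strictly-improving
rule could never fix it). The fitter half of the population is then
duplicated to restore size.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

from .network import Network, GAP_MODULES, EVE_MODULES, FTZ_MODULES
from .fly import make_fly_network, make_targets, make_fly_targets, TargetSet, TargetConfig
from .fitness import FitnessConfig, FitnessReport, evaluate_fitness, WORST_TOTAL
from .phenotype import call_stripes, check_alternation
from .solver import solve_profiles, ConvergenceError

__all__ = [
    "MutationSpec", "EvolutionConfig", "Individual", "Trajectory", "GenRecord",
    "mutate", "step_generation", "evolve", "evolve_fly_to_mosquito",
    "evolve_lca_to_fly", "optimize_stripe_widths", "expand_both_modules",
    "consolidate_lca", "lca_standin", "classify_scenario", "make_evaluator",
]


@dataclass
class MutationSpec:
    """How networks are perturbed.

    ``step_sigma`` is the log-scale standard deviation of the multiplicative
    perturbation applied to each of ``params_per_mutation`` randomly chosen
    evolvable parameters; values are clamped to their declared positive
    ranges. With probability ``p_elimination`` the mutation is instead an
    elimination toggle on a random module: its maximal rate is set to zero,
    or restored to ``resurrection_value`` if it is already zero. Maternal
    profiles are frozen by construction (they are not kernel parameters);
    ``bcd`` in particular never changes.
    """

    step_sigma: float = 0.2
    params_per_mutation: int = 1
    p_elimination: float = 0.02
    resurrection_value: float = 0.3

    def __post_init__(self) -> None:
        if self.step_sigma < 0:
            raise ValueError("step_sigma must be >= 0")
        if not 0 <= self.p_elimination <= 1:
            raise ValueError("p_elimination must be a probability")


@dataclass
class Individual:
    """One population member: a network plus its cached evaluation."""

    network: Network
    report: FitnessReport
    gap: np.ndarray | None = None

    @property
    def n_active(self) -> int:
        return self.network.n_active_modules

    @property
    def key(self) -> tuple[float, int]:
        return (self.report.total, self.n_active)


@dataclass
class GenRecord:
    generation: int
    best_total: float
    best_report: dict
    best_n_active: int
    min_eve_count: int
    min_alternation_ok: bool


@dataclass
class Trajectory:
    """Generation-indexed record of an evolutionary run."""

    seed: int
    config_hash: str
    records: list[GenRecord] = field(default_factory=list)
    snapshots: list[tuple[int, dict, dict]] = field(default_factory=list)  # (gen, network doc, report)
    success: bool = False
    scenario: str = "none"
    final_network: Network | None = None
    final_report: FitnessReport | None = None

    @property
    def failed(self) -> bool:
        return not self.success

    @property
    def best_totals(self) -> np.ndarray:
        return np.array([r.best_total for r in self.records])

    @property
    def min_eve_counts(self) -> np.ndarray:
        return np.array([r.min_eve_count for r in self.records])

    def to_jsonl(self) -> str:
        lines = [json.dumps({"seed": self.seed, "config_hash": self.config_hash,
                             "success": self.success, "scenario": self.scenario})]
        for r in self.records:
            lines.append(json.dumps(asdict(r)))
        return "\n".join(lines) + "\n"


@dataclass
class EvolutionConfig:
    """Run-level settings for the evolutionary experiments.

    The defaults (population 100, cap 20,000 generations, one parameter
    mutated per network per generation) are desk-scale choices; the stop
    threshold is the total fitness below which the target pattern is
    considered reached.
    """

    population_size: int = 100
    generation_cap: int = 20_000
    stop_total: float = 1.0
    neutral_band: float = 0.01
    snapshot_every: int = 500
    include_ftz: bool = True
    ftz_mode: str = "secondary"
    mutation: MutationSpec = field(default_factory=MutationSpec)
    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    targets: TargetConfig = field(default_factory=TargetConfig)

    def hash(self) -> str:
        doc = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def mutate(network: Network, spec: MutationSpec, rng: np.random.Generator) -> Network:
    """Return a mutated copy of ``network`` (the original is untouched).

    Only parameters registered evolvable can change; a module's maximal
    rate reaches exactly zero only through an elimination move. The copy
    carries a ``mutated_gap_kernels`` attribute (True when any gap kernel
    changed) so evaluators can reuse the parent's gap solution when only
    pair-rule kernels were touched.
    """
    net = network.copy()
    gap_dirty = False

    if spec.p_elimination > 0 and rng.random() < spec.p_elimination:
        mods = net.solved_modules
        name = mods[int(rng.integers(len(mods)))]
        k = net.kernels[name]
        k.max_rate = 0.0 if k.max_rate > 0 else spec.resurrection_value
        gap_dirty = name in GAP_MODULES
    elif spec.step_sigma > 0:
        reg = net.registry()
        idx = reg.evolvable_indices
        if len(idx) == 0:
            raise ValueError("network has no evolvable parameters")
        chosen = rng.choice(idx, size=min(spec.params_per_mutation, len(idx)), replace=False)
        vec = net.param_vector()
        for i in chosen:
            vec[i] = np.clip(vec[i] * np.exp(rng.normal(0.0, spec.step_sigma)),
                             reg.lo[i], reg.hi[i])
            if reg.entries[i][0] in GAP_MODULES:
                gap_dirty = True
        net.set_param_vector(vec)
    # step_sigma == 0 without an elimination move: parameters unchanged

    net.mutated_gap_kernels = gap_dirty
    return net


def make_evaluator(
    targets: TargetSet, config: FitnessConfig, max_steps: int = 5_000
) -> Callable[[Network, np.ndarray | None], tuple[FitnessReport, np.ndarray | None]]:
    """Default evaluator: steady state (reusing a gap solution when offered)
    plus fitness against ``targets``.

    ``max_steps`` caps the per-bin relaxation effort; a mutant without a
    fixed point reachable inside the cap scores worst-possible fitness and
    is simply never selected.
    """

    def _evaluate(network: Network, gap: np.ndarray | None = None):
        try:
            profiles, gap = solve_profiles(network, gap=gap, max_steps=max_steps)
        except ConvergenceError:
            return FitnessReport(0.0, 0.0, 0.0, 0.0, WORST_TOTAL, converged=False), None
        return evaluate_fitness(network, targets, config, profiles=profiles), gap

    return _evaluate


def _accept(child_key, parent_key, neutral_band: float) -> bool:
    """Acceptance rule: strictly fitter always wins; an *exactly* equally
    fit mutant wins unless it has more active modules (neutral drift on
    parameters the fitness cannot see); and a mutant within the small
    neutral band wins if it has strictly fewer active modules (parsimony:
    losing an unused module may cost a sliver of profile deviation)."""
    c_total, c_active = child_key
    p_total, p_active = parent_key
    if c_total < p_total:
        return True
    if c_total == p_total and c_active <= p_active:
        return True
    return c_total <= p_total + neutral_band and c_active < p_active


def step_generation(
    population: list[Individual],
    evaluate: Callable,
    spec: MutationSpec,
    rng: np.random.Generator,
    neutral_band: float = 0.01,
) -> list[Individual]:
    """One round of mutation, selection and top-half duplication.

    Every member is mutated and the mutant replaces its parent if accepted;
    the population is then ranked by (total fitness, active module count)
    and the best half duplicated to restore size. Population size must be
    even and at least 2; it is preserved exactly.
    """
    n = len(population)
    if n < 2 or n % 2:
        raise ValueError("population size must be even and >= 2")

    nxt: list[Individual] = []
    for parent in population:
        child_net = mutate(parent.network, spec, rng)
        gap_hint = None if child_net.mutated_gap_kernels else parent.gap
        report, gap = evaluate(child_net, gap_hint)
        child = Individual(child_net, report, gap)
        nxt.append(child if _accept(child.key, parent.key, neutral_band) else parent)

    nxt.sort(key=lambda ind: ind.key)
    half = nxt[: n // 2]
    return half + [Individual(ind.network, ind.report, ind.gap) for ind in half]


def evolve(
    start: Network,
    targets: TargetSet,
    config: EvolutionConfig,
    seed: int,
    evaluate: Callable | None = None,
) -> Trajectory:
    """Generic mutation-selection run from ``start`` toward ``targets``."""
    rng = np.random.default_rng(seed)
    evaluate = evaluate or make_evaluator(targets, config.fitness)
    report0, gap0 = evaluate(start, None)
    population = [Individual(start, report0, gap0) for _ in range(config.population_size)]

    from . import io as _io  # local import: io depends on network, not on us

    traj = Trajectory(seed=seed, config_hash=config.hash())

    def _record(gen: int, pop: list[Individual]) -> Individual:
        best = min(pop, key=lambda ind: ind.key)
        traj.records.append(GenRecord(
            generation=gen,
            best_total=best.report.total,
            best_report=best.report.to_dict(),
            best_n_active=best.n_active,
            min_eve_count=min(ind.report.eve_count for ind in pop),
            min_alternation_ok=all(ind.report.alternation_ok for ind in pop),
        ))
        return best

    best = _record(0, population)
    traj.snapshots.append((0, _io.network_to_dict(best.network), best.report.to_dict()))

    for gen in range(1, config.generation_cap + 1):
        population = step_generation(
            population, evaluate, config.mutation, rng, config.neutral_band
        )
        best = _record(gen, population)
        if gen % config.snapshot_every == 0:
            traj.snapshots.append((gen, _io.network_to_dict(best.network), best.report.to_dict()))
        if best.report.total <= config.stop_total:
            traj.success = True
            break

    traj.final_network = best.network
    traj.final_report = best.report
    if traj.snapshots[-1][0] != traj.records[-1].generation:
        traj.snapshots.append(
            (traj.records[-1].generation, _io.network_to_dict(best.network), best.report.to_dict())
        )
    traj.scenario = classify_scenario(best.network)
    return traj


def classify_scenario(network: Network) -> str:
    """Which derived module drives three stripes in the evolved pattern.

    ``"stripe7_split"``: the 3+7 module was split by the repositioned
    posterior ``hb`` (three stripes from eve37); ``"stripe6_split"``: the
    4+6 module split instead; ``"both"``; or ``"none"``.
    """
    try:
        profiles, _ = solve_profiles(network)
    except ConvergenceError:
        return "none"
    n37 = len(call_stripes(profiles["eve37"], network.grid))
    n46 = len(call_stripes(profiles["eve46"], network.grid))
    if n37 >= 3 and n46 >= 3:
        return "both"
    if n37 >= 3:
        return "stripe7_split"
    if n46 >= 3:
        return "stripe6_split"
    return "none"


def evolve_fly_to_mosquito(config: EvolutionConfig | None = None, seed: int = 0) -> Trajectory:
    """Evolve the calibrated fly network toward the mosquito gap pattern.

    The target demands the posterior ``hb`` domain shifted anteriorly, the
    posterior ``gt`` domain absent, and the anterior ``eve`` pattern
    unchanged, under the viability constraints of at least 7 ``eve`` stripes
    and (with ``ftz``) strict alternation. Reaching the stop threshold sets
    ``success``; hitting the generation cap leaves the trajectory flagged
    failed (no exception).
    """
    cfg = config or EvolutionConfig()
    fly = make_fly_network(include_ftz=cfg.include_ftz, ftz_mode=cfg.ftz_mode)
    targets = make_targets(config=cfg.targets, fly=fly)
    return evolve(fly, targets, cfg, seed)


def evolve_lca_to_fly(
    lca: Network, config: EvolutionConfig | None = None, seed: int = 0
) -> Trajectory:
    """Evolve an LCA stand-in (an evolved mosquito-like end state) back to
    the fly gap configuration: posterior ``gt`` restored, posterior ``hb``
    returned to its fly position, anterior ``eve`` conserved."""
    cfg = config or EvolutionConfig()
    targets = make_fly_targets(config=cfg.targets)
    return evolve(lca, targets, cfg, seed)


def _mutate_modules(
    network: Network, modules: tuple[str, ...], sigma: float, rng: np.random.Generator
) -> Network:
    """Multiplicative perturbation of one evolvable parameter drawn from the
    named modules only."""
    net = network.copy()
    reg = net.registry()
    idx = [i for i in reg.evolvable_indices if reg.entries[i][0] in modules]
    i = idx[int(rng.integers(len(idx)))]
    vec = net.param_vector()
    vec[i] = np.clip(vec[i] * np.exp(rng.normal(0.0, sigma)), reg.lo[i], reg.hi[i])
    net.set_param_vector(vec)
    net.mutated_gap_kernels = reg.entries[i][0] in GAP_MODULES
    return net


def expand_both_modules(
    network: Network,
    targets: TargetSet,
    config: EvolutionConfig | None = None,
    seed: int = 0,
    iterations: int = 20000,
    step_sigma: float = 0.35,
    target_total: int = 8,
) -> Network:
    """Local search from a mosquito-like end state until both derived
    posterior modules are split by the repositioned posterior hb, raising
    the total eve stripe count (stripe-1 convention included) to
    ``target_total`` — the eight-stripe mosquito configuration.

    Proposals perturb the two derived modules' kernels (the operation is
    about their posterior sensitivities); a random walk accepts any
    non-worsening move in (stripe count, fitness) — posterior-only changes
    are fitness-neutral, so the walk can traverse plateaus — and the best
    configuration seen is returned (the input itself if nothing improves).
    """
    cfg = config or EvolutionConfig()
    rng = np.random.default_rng(seed)
    evaluate = make_evaluator(targets, cfg.fitness)

    def _key(report):
        if report.total >= WORST_TOTAL or not report.alternation_ok:
            return None
        return (min(report.eve_count, target_total), -report.total)

    report, gap = evaluate(network, None)
    cur_key = _key(report)
    if cur_key is None:
        return network
    cur_net, cur_gap, cur_total = network, gap, report.total
    best_net, best_key = network, cur_key
    for _ in range(iterations):
        cand = _mutate_modules(cur_net, ("eve37", "eve46"), step_sigma, rng)
        rep, cand_gap = evaluate(cand, None if cand.mutated_gap_kernels else cur_gap)
        key = _key(rep)
        if key is None:
            continue
        if key >= cur_key and rep.total <= cur_total + cfg.neutral_band:
            cur_net, cur_key, cur_gap, cur_total = cand, key, cand_gap, rep.total
            if key > best_key:
                best_net, best_key = cand, key
            if rep.eve_count >= target_total:
                break
    return best_net


def lca_standin(trajectory: Trajectory) -> Network:
    """Reconstruct the last-common-ancestor stand-in from a fly-to-mosquito
    trajectory: the network at the *earliest* recorded stage whose posterior
    gt module is already eliminated.

    The ancestor is a mid-pathway reconstruction, not the derived mosquito
    tip: it shares the mosquito lineage's diagnostic posterior-gt loss but
    predates the fitness-invisible drift that accumulates once the gap
    target is met. Falls back to the final network if no snapshot qualifies.
    """
    from . import io as _io

    for gen, doc, rep in trajectory.snapshots:
        net = _io.network_from_dict(doc)
        try:
            profiles, _ = solve_profiles(net)
        except ConvergenceError:
            continue
        if profiles["gt_post"].max < net.loss_threshold:
            return net
    if trajectory.final_network is None:
        raise ValueError("trajectory carries no final network")
    return trajectory.final_network


def consolidate_lca(
    network: Network,
    targets: TargetSet,
    config: EvolutionConfig | None = None,
    seed: int = 0,
    iterations: int = 2000,
    step_sigma: float = 0.15,
) -> Network:
    """Locally adjust an evolved end state into a presentable ancestor
    stand-in: a random walk over the pair-rule module parameters that
    equalizes eve stripe amplitudes and widths while preserving the stripe
    count, alternation and total fitness (within the neutral band).

    Evolved end states carry fitness-invisible drift — overlapping modules
    stack into one dominant peak, which distorts the relative-threshold
    stripe call under perturbations such as a domain deletion. This mirrors
    the presentation step used for the ancestor configurations (parameters
    adjusted so stripes are of comparable size) without changing the
    evolved logic.
    """
    cfg = config or EvolutionConfig()
    rng = np.random.default_rng(seed)
    evaluate = make_evaluator(targets, cfg.fitness)
    pr_modules = tuple(EVE_MODULES) + (tuple(FTZ_MODULES) if network.include_ftz else ())
    active = tuple(m for m in pr_modules if not network.kernels[m].eliminated)

    def _score(net: Network, report, gap_arr):
        if report.total >= WORST_TOTAL or not report.alternation_ok:
            return None
        try:
            profiles, _ = solve_profiles(net, gap=gap_arr)
        except ConvergenceError:
            return None
        ev = call_stripes(profiles["eve"], net.grid,
                         threshold_frac=cfg.fitness.threshold_frac,
                         min_width_bins=cfg.fitness.min_width_bins)
        if len(ev) < 2:
            return None
        amps = np.array([s.amplitude for s in ev])
        widths = ev.widths
        spread = float(np.var(amps / amps.mean()) + np.var(widths / widths.mean()))
        return report.eve_count, spread

    report, gap = evaluate(network, None)
    base = _score(network, report, gap)
    if base is None:
        return network
    count0, spread0 = base
    cur_net, cur_gap, cur_total, cur_spread = network, gap, report.total, spread0
    best_net, best_spread = network, spread0
    for _ in range(iterations):
        cand = _mutate_modules(cur_net, active, step_sigma, rng)
        rep, cand_gap = evaluate(cand, None if cand.mutated_gap_kernels else cur_gap)
        sc = _score(cand, rep, cand_gap)
        if sc is None or sc[0] != count0 or rep.total > cur_total + cfg.neutral_band:
            continue
        if sc[1] <= cur_spread:
            cur_net, cur_gap, cur_total, cur_spread = cand, cand_gap, rep.total, sc[1]
            if sc[1] < best_spread:
                best_net, best_spread = cand, sc[1]
    return best_net


def optimize_stripe_widths(
    network: Network,
    config: EvolutionConfig | None = None,
    seed: int = 0,
    iterations: int = 300,
    step_sigma: float = 0.05,
) -> Network:
    """Local hill-climb equalizing ``eve`` stripe widths.

    Minimizes the variance of called stripe widths while keeping the stripe
    count and (if applicable) alternation fixed. Returns the improved
    network; if no improving step is found the input is returned unchanged.
    """
    cfg = config or EvolutionConfig()
    rng = np.random.default_rng(seed)

    def _measure(net: Network):
        try:
            profiles, _ = solve_profiles(net)
        except ConvergenceError:
            return None
        ev = call_stripes(profiles["eve"], net.grid,
                          threshold_frac=cfg.fitness.threshold_frac,
                          min_width_bins=cfg.fitness.min_width_bins)
        alt = True
        if net.include_ftz:
            fz = call_stripes(profiles["ftz"], net.grid,
                              threshold_frac=cfg.fitness.threshold_frac,
                              min_width_bins=cfg.fitness.min_width_bins)
            alt = check_alternation(ev, fz)[0]
        if len(ev) < 2:
            return None
        return len(ev), alt, float(np.var(ev.widths))

    base = _measure(network)
    if base is None:
        return network
    count0, alt0, var0 = base
    current, var_cur = network, var0
    spec = MutationSpec(step_sigma=step_sigma, p_elimination=0.0)
    for _ in range(iterations):
        cand = mutate(current, spec, rng)
        m = _measure(cand)
        if m is None:
            continue
        count, alt, var = m
        if count == count0 and alt == alt0 and var < var_cur:
            current, var_cur = cand, var
    return current
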