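"""Mutation-selection-drift evolution of GRN populations toward a target map.

A haploid population of ``p`` individuals (non-overlapping generations)
evolves the slope of one selected map (GP, EP or PP). Each generation every
individual develops one phenotype per input supplied by the grain schedule;
fitness is either ``exp(-|S_i - S_target|)`` on the fitted slope or
``exp(-ED(map_i, target map))`` on the point-by-point Euclidean distance.
Reproduction is fitness-proportional with replacement; offspring are mutated
(interaction weights and multilinear coefficients jittered by N(0, sigma),
topology bits flipped, each with the per-element mutation rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from grnmaps.development import DevelopmentParams, check_stability, develop_batch, read_phenotype
from grnmaps.ensemble import EnvironmentVector, GRNGenome
from grnmaps.maps import Element, FrozenContext, choose_element, default_grid, draw_collapsed_value
from grnmaps.metrics import fit_slope, transform_slope

MAP_KINDS = ("GP", "EP", "PP")


@dataclass
class EvolutionConfig:
    pop_size: int = 64
    max_generations: int = 100_000
    target_slope: float = 1.0
    selected_map_kind: str = "GP"
    mutation_rate: float = 0.04
    mutation_sd: float = 0.01
    grain: float = 10.0
    target_schedule: tuple[tuple[int, float], ...] = ()
    fitness_mode: str = "slope"  # "slope" | "euclidean"
    fixed_input_grid: bool = True  # systematic grid vs fresh uniform draws (grain >= 1)
    stop_on_convergence: bool = True
    convergence_fitness: float = 0.9
    convergence_window: int = 50
    dev_params: DevelopmentParams = field(default_factory=DevelopmentParams)
    record_every: int = 1

    def validate(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.grain <= 0:
            raise ValueError("grain must be positive")
        if self.selected_map_kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.selected_map_kind!r}")
        if self.fitness_mode not in ("slope", "euclidean"):
            raise ValueError(f"unknown fitness mode {self.fitness_mode!r}")


@dataclass
class Individual:
    """A genome plus its (non-heritable, frozen) environment and input channel."""

    genome: GRNGenome
    env: EnvironmentVector
    element: Element  # the selected input channel

    def copy(self) -> "Individual":
        return Individual(self.genome.copy(), self.env.copy(), self.element)


@dataclass
class EvolutionRun:
    """Per-generation trajectory of a single evolutionary replicate."""

    generations: np.ndarray
    mean_fitness: np.ndarray
    max_fitness: np.ndarray
    mean_slope: np.ndarray
    final_population: list[Individual]
    converged_at: int | None
    seed: int | None = None
    replicate_id: int | None = None

    def records(self) -> list[dict]:
        return [
            {
                "generation": int(g),
                "mean_W": float(mw),
                "max_W": float(xw),
                "mean_S_selected": float(ms),
            }
            for g, mw, xw, ms in zip(self.generations, self.mean_fitness, self.max_fitness, self.mean_slope)
        ]


def mutate(genome: GRNGenome, config: EvolutionConfig, rng: np.random.Generator) -> GRNGenome:
    """Point mutations: B and Z jittered by N(0, sigma), M bits flipped.

    Each element mutates independently with ``mutation_rate``; the input
    genome is never modified.
    """
    out = genome.copy()
    rate, sd = config.mutation_rate, config.mutation_sd
    if rate == 0:
        return out
    n = genome.n_genes
    b_hits = rng.random((n, n)) < rate
    out.interaction_strengths = out.interaction_strengths + b_hits * rng.normal(0.0, sd, size=(n, n))
    m_hits = rng.random((n, n)) < rate
    out.topology_mask = np.where(m_hits, 1 - out.topology_mask, out.topology_mask).astype(np.int8)
    if out.multilinear_coeffs is not None:
        z = out.multilinear_coeffs
        z_hits = rng.random(z.shape) < rate
        out.multilinear_coeffs = z + z_hits * rng.normal(0.0, sd, size=z.shape)
    return out


class GrainSchedule:
    """Inputs-per-generation schedule.

    grain >= 1: ``round(grain)`` inputs each generation — evenly spaced over
    (0, 1] when ``fixed_grid`` (the systematic-perturbation protocol), fresh
    uniform draws otherwise; grain < 1: one input held constant for
    ``round(1/grain)`` generations between redraws. Inputs are
    population-wide within a generation.
    """

    def __init__(self, grain: float, rng: np.random.Generator, fixed_grid: bool = False):
        if grain <= 0:
            raise ValueError("grain must be positive")
        self.grain = grain
        self._rng = rng
        self._fixed_grid = fixed_grid
        self._held: np.ndarray | None = None

    def _draw(self, k: int) -> np.ndarray:
        x = self._rng.uniform(0.0, 1.0, size=k)
        while (x == 0.0).any():
            x[x == 0.0] = self._rng.uniform(0.0, 1.0, size=int((x == 0.0).sum()))
        return x

    def inputs_for(self, generation: int) -> np.ndarray:
        if self.grain >= 1:
            k = int(round(self.grain))
            if self._fixed_grid:
                return np.arange(1, k + 1) / k
            return self._draw(k)
        period = max(1, int(round(1.0 / self.grain)))
        if self._held is None or generation % period == 0:
            self._held = self._draw(1)
        return self._held


def grain_schedule(grain: float, generation: int, rng: np.random.Generator) -> np.ndarray:
    """Stateless convenience wrapper (fresh schedule seeded by ``rng``)."""
    return GrainSchedule(grain, rng).inputs_for(generation)


def _develop_points(
    individual: Individual,
    inputs: np.ndarray,
    params: DevelopmentParams,
    rng: np.random.Generator | None,
    element: Element | None = None,
    frozen: FrozenContext | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Develop one phenotype per input of the (selected) element.

    Returns (points, viable): points is (n_inputs, n_traits) with nan rows for
    unviable developments.
    """
    genome = individual.genome
    element = element if element is not None else individual.element
    weights0 = genome.effective_weights.copy()
    env0 = individual.env.values.copy()
    g00 = genome.initial_state.copy()
    if frozen is not None:
        for el, value in frozen.overrides.items():
            _apply(weights0, env0, g00, el, float(value))
    n_in = len(inputs)
    weights = np.repeat(weights0[None, :, :], n_in, axis=0)
    envs = np.repeat(env0[None, :], n_in, axis=0)
    g0s = np.repeat(g00[None, :], n_in, axis=0)
    for k, x in enumerate(inputs):
        _apply(weights[k], envs[k], g0s[k], element, float(x))
    finals, earlies = develop_batch(weights, envs, g0s, params, rng)
    points = np.full((n_in, genome.n_traits), np.nan)
    viable = np.zeros(n_in, dtype=bool)
    for k in range(n_in):
        if np.isfinite(finals[k]).all() and check_stability(earlies[k], finals[k], params.stability_tol):
            viable[k] = True
            points[k] = read_phenotype(finals[k], genome, params.trait_genes)
    return points, viable


def _apply(weights, env, g0, element: Element, value: float) -> None:
    if element.kind == "B":
        weights[element.i, element.j] = value
    elif element.kind == "E":
        env[element.i] = value
    elif element.kind == "G0":
        g0[element.i] = value
    else:
        raise ValueError(f"element kind {element.kind!r} not supported in evolution")


def evaluate_individual(
    individual: Individual,
    config: EvolutionConfig,
    grain_inputs: np.ndarray,
    rng: np.random.Generator | None = None,
    target_slope: float | None = None,
) -> tuple[float, float | None, np.ndarray]:
    """Fitness of one individual over this generation's inputs.

    Slope mode: ``W = exp(-|S_i - S_target|)`` with S_i the OLS slope over
    the developed (viable) points; fewer than 2 viable points gives W = 0.
    Euclidean mode: ``W = exp(-ED(map_i, target))`` with the target map point
    for input x at ``(x, S_target * x)``; any unviable point gives W = 0.

    Returns (fitness, slope or None, developed points).
    """
    target = config.target_slope if target_slope is None else target_slope
    points, viable = _develop_points(individual, grain_inputs, config.dev_params, rng)
    if config.fitness_mode == "slope":
        if viable.sum() < 2:
            return 0.0, None, points
        try:
            s = fit_slope(points[viable])
        except ValueError:
            return 0.0, None, points
        return float(math.exp(-abs(s - target))), s, points
    # euclidean mode
    if not viable.all():
        return 0.0, None, points
    target_points = np.column_stack([grain_inputs, target * np.asarray(grain_inputs)])
    ed = float(np.sqrt(np.sum((points - target_points) ** 2)))
    slope = None
    if viable.sum() >= 2:
        try:
            slope = fit_slope(points[viable])
        except ValueError:
            slope = None
    return float(math.exp(-ed)), slope, points


def evaluate_population(
    population: list[Individual],
    config: EvolutionConfig,
    grain_inputs: np.ndarray,
    rng: np.random.Generator | None = None,
    target_slope: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the whole population in one padded batched integration.

    Semantically identical to calling :func:`evaluate_individual` per
    individual; used by :func:`evolve` for speed. Returns (fitnesses, slopes)
    with nan slopes where undefined.
    """
    target = config.target_slope if target_slope is None else target_slope
    params = config.dev_params
    p = len(population)
    k = len(grain_inputs)
    n_max = max(ind.genome.n_genes for ind in population)
    weights = np.zeros((p * k, n_max, n_max))
    envs = np.zeros((p * k, n_max))
    g0s = np.zeros((p * k, n_max))
    for idx, ind in enumerate(population):
        n = ind.genome.n_genes
        w0 = ind.genome.effective_weights
        sl = slice(idx * k, (idx + 1) * k)
        weights[sl, :n, :n] = w0
        envs[sl, :n] = ind.env.values
        g0s[sl, :n] = ind.genome.initial_state
        el = ind.element
        for kk, x in enumerate(grain_inputs):
            row = idx * k + kk
            if el.kind == "B":
                weights[row, el.i, el.j] = x
            elif el.kind == "E":
                envs[row, el.i] = x
            elif el.kind == "G0":
                g0s[row, el.i] = x
            else:
                raise ValueError(f"element kind {el.kind!r} not supported in evolution")
    finals, earlies = develop_batch(weights, envs, g0s, params, rng)
    # viability: L1-normalized max-norm change within tolerance
    sums_f = finals.sum(axis=1, keepdims=True)
    sums_e = earlies.sum(axis=1, keepdims=True)
    norm_f = np.divide(finals, sums_f, out=np.zeros_like(finals), where=sums_f > 0)
    norm_e = np.divide(earlies, sums_e, out=np.zeros_like(earlies), where=sums_e > 0)
    viable = (
        np.isfinite(finals).all(axis=1)
        & (np.abs(norm_f - norm_e).max(axis=1) <= params.stability_tol)
    )
    fitnesses = np.zeros(p)
    slopes = np.full(p, np.nan)
    for idx, ind in enumerate(population):
        n = ind.genome.n_genes
        sl = slice(idx * k, (idx + 1) * k)
        v = viable[sl]
        g_final = finals[sl, :n]
        points = np.full((k, ind.genome.n_traits), np.nan)
        if v.any():
            for kk in np.nonzero(v)[0]:
                points[kk] = read_phenotype(g_final[kk], ind.genome, params.trait_genes)
        if config.fitness_mode == "slope":
            if v.sum() >= 2:
                try:
                    s = fit_slope(points[v])
                except ValueError:
                    continue
                slopes[idx] = s
                fitnesses[idx] = math.exp(-abs(s - target))
        else:
            if v.all():
                target_points = np.column_stack([grain_inputs, target * np.asarray(grain_inputs)])
                ed = float(np.sqrt(np.sum((points - target_points) ** 2)))
                fitnesses[idx] = math.exp(-ed)
                if v.sum() >= 2:
                    try:
                        slopes[idx] = fit_slope(points[v])
                    except ValueError:
                        pass
    return fitnesses, slopes


def select_reproduce(
    population: list[Individual],
    fitnesses: np.ndarray,
    rng: np.random.Generator,
    config: EvolutionConfig | None = None,
) -> list[Individual]:
    """Fitness-proportional sampling with replacement, then mutation.

    All-zero fitness degenerates to uniform drift. Generations do not overlap.
    """
    fitnesses = np.asarray(fitnesses, dtype=float)
    if len(population) != len(fitnesses):
        raise ValueError("population and fitness vector sizes differ")
    if (fitnesses < 0).any():
        raise ValueError("fitnesses must be non-negative")
    total = fitnesses.sum()
    probs = np.full(len(population), 1.0 / len(population)) if total == 0 else fitnesses / total
    parents = rng.choice(len(population), size=len(population), p=probs)
    offspring = []
    for idx in parents:
        child = population[idx].copy()
        if config is not None:
            child.genome = mutate(child.genome, config, rng)
        offspring.append(child)
    return offspring


def init_population(
    ensemble_pairs: list[tuple[GRNGenome, EnvironmentVector]],
    config: EvolutionConfig,
    rng: np.random.Generator,
) -> list[Individual]:
    """Draw p individuals from a random ensemble and pick their input channel.

    The element index is chosen once per individual (held for the whole run)
    among the elements legal for the selected map kind.
    """
    if not ensemble_pairs:
        raise ValueError("empty ensemble")
    picks = rng.integers(len(ensemble_pairs), size=config.pop_size)
    population = []
    for idx in picks:
        genome, env = ensemble_pairs[idx]
        genome = genome.copy()
        env = env.copy()
        try:
            element = choose_element(genome, config.selected_map_kind, rng)
        except ValueError:
            # empty topology: fall back to a uniformly chosen (inactive) weight
            i = int(rng.integers(genome.n_genes))
            j = int(rng.integers(genome.n_genes))
            element = Element("B", i, j)
        population.append(Individual(genome, env, element))
    return population


def evolve(
    initial_population: list[Individual],
    config: EvolutionConfig,
    rng: np.random.Generator,
    seed: int | None = None,
    replicate_id: int | None = None,
) -> EvolutionRun:
    """Iterate evaluate -> select -> mutate until convergence or t_max.

    Convergence: the trailing ``convergence_window``-generation average of
    population mean fitness reaches ``convergence_fitness`` (mean fitness
    sustained at the threshold over the window); ``converged_at`` is the
    first generation of that window. Target-slope shifts in
    ``target_schedule`` apply from their generation onward (and reset the
    convergence history).
    """
    from collections import deque

    config.validate()
    population = [ind.copy() for ind in initial_population]
    schedule = GrainSchedule(config.grain, rng, fixed_grid=config.fixed_input_grid)
    target = config.target_slope
    shifts = dict(config.target_schedule)
    gens, mean_w, max_w, mean_s = [], [], [], []
    window: deque[float] = deque(maxlen=config.convergence_window)
    converged_at: int | None = None
    for gen in range(config.max_generations):
        if gen in shifts:
            target = float(shifts[gen])
            window.clear()
        inputs = schedule.inputs_for(gen)
        fitnesses, slopes = evaluate_population(population, config, inputs, rng, target_slope=target)
        if gen % config.record_every == 0 or gen == config.max_generations - 1:
            gens.append(gen)
            mean_w.append(float(fitnesses.mean()))
            max_w.append(float(fitnesses.max()))
            finite = slopes[np.isfinite(slopes)]
            mean_s.append(float(finite.mean()) if len(finite) else float("nan"))
        window.append(float(fitnesses.mean()))
        if (
            len(window) == config.convergence_window
            and float(np.mean(window)) >= config.convergence_fitness
        ):
            if converged_at is None:
                converged_at = gen - config.convergence_window + 1
            pending_shift = any(g > gen for g in shifts)
            if config.stop_on_convergence and not pending_shift:
                break
        population = select_reproduce(population, fitnesses, rng, config)
    return EvolutionRun(
        generations=np.array(gens, dtype=int),
        mean_fitness=np.array(mean_w),
        max_fitness=np.array(max_w),
        mean_slope=np.array(mean_s),
        final_population=population,
        converged_at=converged_at,
        seed=seed,
        replicate_id=replicate_id,
    )


def probe_nonselected_maps(
    final_population: list[Individual],
    config: EvolutionConfig,
    rng: np.random.Generator,
    n_collapsed: int = 3,
    kinds: tuple[str, ...] | None = None,
    grid: np.ndarray | None = None,
) -> dict[str, list[dict]]:
    """Probe maps of each non-selected kind on the evolved population.

    The selected input is collapsed to x ~ U(0,1) (never exactly 0; repeated
    for ``n_collapsed`` draws); grid variation is introduced in one randomly
    chosen element of the probed kind. Returns, per kind, one record per
    (individual, collapsed draw) with the probe map and its slope, plus the
    individual's selected-map slope measured on the standard grid.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if kinds is None:
        kinds = tuple(k for k in MAP_KINDS)
    params = config.dev_params
    out: dict[str, list[dict]] = {kind: [] for kind in kinds}
    for idx, ind in enumerate(final_population):
        # selected-map slope over the standard grid (the evolved bias)
        sel_points, sel_viable = _develop_points(ind, grid, params, rng)
        try:
            sel_slope = fit_slope(sel_points[sel_viable]) if sel_viable.sum() >= 2 else None
        except ValueError:
            sel_slope = None
        for kind in kinds:
            if kind == config.selected_map_kind:
                probe_elements = [ind.element]
            else:
                try:
                    probe_elements = [choose_element(ind.genome, kind, rng)]
                except ValueError:
                    continue
            for _ in range(n_collapsed):
                x = draw_collapsed_value(rng)
                assert x != 0.0
                frozen = FrozenContext(overrides={ind.element: x}) if kind != config.selected_map_kind else None
                points, viable = _develop_points(
                    ind, grid, params, rng, element=probe_elements[0], frozen=frozen
                )
                try:
                    slope = fit_slope(points[viable]) if viable.sum() >= 2 else None
                except ValueError:
                    slope = None
                out[kind].append(
                    {
                        "individual": idx,
                        "collapsed_x": x,
                        "slope": slope,
                        "transformed_slope": None if slope is None else transform_slope(slope),
                        "selected_slope": sel_slope,
                        "selected_transformed_slope": None if sel_slope is None else transform_slope(sel_slope),
                        "points": points,
                        "viable": viable,
                    }
                )
    return out
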