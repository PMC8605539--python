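"""Construction of GP, EP and PP maps by systematic parametric perturbation.

One GRN element (an active interaction weight for GP maps, an environmental
input or diffusion rate for EP maps, an initial concentration for PP maps) is
overwritten with each value of an input grid (default 0 to 1 in steps of 0.1)
while every other input is held frozen; one development is run per grid value
and the resulting trait vectors constitute the map. Massive joint perturbation
of all element types yields the general phenotype distribution (GPD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from grnmaps.development import DevelopmentParams, check_stability, develop, develop_batch, read_phenotype
from grnmaps.ensemble import EnvironmentVector, GRNGenome, n_diffusible

MAP_KINDS = ("GP", "EP", "PP")


class Element(NamedTuple):
    """Address of one perturbable GRN element."""

    kind: str  # "B" | "E" | "G0" | "D"
    i: int
    j: int = -1  # column index, B only


@dataclass
class FrozenContext:
    """Fixed values for all non-perturbed inputs during a map build.

    ``overrides`` pins individual elements (e.g. the previously selected
    input collapsed to a single value x ~ U(0,1), never exactly 0).
    """

    env: EnvironmentVector | np.ndarray | None = None
    overrides: dict[Element, float] = field(default_factory=dict)


def default_grid(n_points: int = 11) -> np.ndarray:
    """The perturbation grid over [0, 1]; 11 points reproduces 0:0.1:1."""
    return np.linspace(0.0, 1.0, n_points)


@dataclass
class PhenotypeMap:
    """One input-grid -> phenotype-set mapping of kind GP/EP/PP."""

    map_kind: str
    perturbed_element: Element
    input_values: np.ndarray
    phenotypes: np.ndarray  # (n_grid, n_traits); rows for unviable inputs are nan
    viable_flags: np.ndarray
    genome_id: int | None = None

    @property
    def degenerate(self) -> bool:
        return int(self.viable_flags.sum()) < 2

    def viable_points(self) -> np.ndarray:
        return self.phenotypes[self.viable_flags]

    def viable_inputs(self) -> np.ndarray:
        return self.input_values[self.viable_flags]


def legal_elements(genome: GRNGenome, map_kind: str) -> list[Element]:
    """Perturbable elements for a map kind; topology is never an element."""
    n = genome.n_genes
    if map_kind == "GP":
        rows, cols = np.nonzero(genome.topology_mask)
        return [Element("B", int(i), int(j)) for i, j in zip(rows, cols)]
    if map_kind == "PP":
        return [Element("G0", i) for i in range(n)]
    if map_kind == "EP":
        elements = [Element("E", i) for i in range(n)]
        if genome.model_kind == "lattice":
            elements += [Element("D", i) for i in range(n_diffusible(n))]
        return elements
    raise ValueError(f"unknown map kind {map_kind!r}")


def choose_element(genome: GRNGenome, map_kind: str, rng: np.random.Generator) -> Element:
    """Uniform choice among the legal elements of a map kind."""
    elements = legal_elements(genome, map_kind)
    if not elements:
        raise ValueError(f"no legal {map_kind} element (empty topology?)")
    return elements[int(rng.integers(len(elements)))]


def choose_linked_elements(genome: GRNGenome, rng: np.random.Generator) -> dict[str, Element]:
    """One perturbable element per map kind, all feeding the same focal gene.

    A focal gene ``i`` with at least one active incoming interaction is drawn
    uniformly; the GP element is a random active incoming weight ``B_ij``, the
    EP element the focal gene's environmental input ``E_i``, and the PP
    element its initial concentration ``G0_i``. Perturbing commensurate
    inputs of one node is what makes the three maps directly comparable.
    """
    rows, cols = np.nonzero(genome.topology_mask)
    if len(rows) == 0:
        raise ValueError("no legal GP element (empty topology)")
    candidates = np.unique(rows)
    focal = int(rng.choice(candidates))
    incoming = cols[rows == focal]
    j = int(rng.choice(incoming))
    return {
        "GP": Element("B", focal, j),
        "EP": Element("E", focal),
        "PP": Element("G0", focal),
    }


def _base_inputs(
    genome: GRNGenome,
    frozen: FrozenContext | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weights, env, g0 and diffusion after applying frozen overrides."""
    weights = genome.effective_weights.copy()
    if frozen is not None and frozen.env is not None:
        env = frozen.env.values.copy() if isinstance(frozen.env, EnvironmentVector) else np.array(frozen.env, dtype=float)
    else:
        env = np.zeros(genome.n_genes)
    g0 = genome.initial_state.copy()
    diff = genome.diffusion_rates.copy() if genome.diffusion_rates is not None else np.zeros(genome.n_genes)
    if frozen is not None:
        for element, value in frozen.overrides.items():
            _apply_element(weights, env, g0, diff, element, float(value))
    return weights, env, g0, diff


def _apply_element(weights, env, g0, diff, element: Element, value: float) -> None:
    if element.kind == "B":
        weights[element.i, element.j] = value
    elif element.kind == "E":
        env[element.i] = value
    elif element.kind == "G0":
        g0[element.i] = value
    elif element.kind == "D":
        diff[element.i] = value
    else:
        raise ValueError(f"unknown element kind {element.kind!r}")


def build_map(
    genome: GRNGenome,
    map_kind: str,
    element: Element,
    grid: np.ndarray | None = None,
    frozen: FrozenContext | None = None,
    params: DevelopmentParams | None = None,
    rng: np.random.Generator | None = None,
    strict: bool = True,
) -> PhenotypeMap:
    """Run one development per grid value of the perturbed element.

    The element's value is overwritten (not scaled) by each grid value; the
    genome itself is never mutated. With ``strict`` (the default) perturbing
    an interaction weight whose topology entry is 0 is rejected for GP maps.
    """
    params = params or DevelopmentParams()
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if strict and map_kind == "GP":
        if element.kind != "B" or genome.topology_mask[element.i, element.j] != 1:
            raise ValueError("GP maps perturb an active interaction weight")
    weights0, env0, g00, diff0 = _base_inputs(genome, frozen)
    n_grid = len(grid)
    n_traits = genome.n_traits

    if genome.model_kind == "lattice":
        phenotypes = np.full((n_grid, n_traits), np.nan)
        viable = np.zeros(n_grid, dtype=bool)
        for k, x in enumerate(grid):
            weights, env, g0, diff = weights0.copy(), env0.copy(), g00.copy(), diff0.copy()
            _apply_element(weights, env, g0, diff, element, float(x))
            probe = genome.copy()
            probe.interaction_strengths = weights
            probe.topology_mask = np.ones_like(probe.topology_mask)
            probe.diffusion_rates = diff
            probe.initial_state = g0
            result = develop(probe, env, params, rng)
            viable[k] = result.stable
            if result.stable:
                phenotypes[k] = result.traits
        return PhenotypeMap(map_kind, element, grid, phenotypes, viable, genome.genome_id)

    weights_batch = np.repeat(weights0[None, :, :], n_grid, axis=0)
    envs = np.repeat(env0[None, :], n_grid, axis=0)
    g0s = np.repeat(g00[None, :], n_grid, axis=0)
    for k, x in enumerate(grid):
        _apply_element(weights_batch[k], envs[k], g0s[k], None, element, float(x))
    finals, earlies = develop_batch(weights_batch, envs, g0s, params, rng)
    viable = np.array(
        [
            np.isfinite(finals[k]).all() and check_stability(earlies[k], finals[k], params.stability_tol)
            for k in range(n_grid)
        ]
    )
    phenotypes = np.full((n_grid, n_traits), np.nan)
    for k in range(n_grid):
        if viable[k]:
            phenotypes[k] = read_phenotype(finals[k], genome, params.trait_genes)
    return PhenotypeMap(map_kind, element, grid, phenotypes, viable, genome.genome_id)


def sample_gpd(
    genome: GRNGenome,
    n_samples: int,
    params: DevelopmentParams | None = None,
    rng: np.random.Generator | None = None,
    frozen: FrozenContext | None = None,
    perturb_probability: float = 0.5,
) -> np.ndarray:
    """General phenotype distribution via massive unspecific perturbation.

    Each sample independently redraws every perturbable element ~ U(0,1) with
    probability ``perturb_probability`` (one unspecific scheme among many) and
    keeps the viable trait vectors.
    """
    params = params or DevelopmentParams()
    rng = rng or np.random.default_rng()
    if n_samples == 0:
        return np.empty((0, genome.n_traits))
    weights0, env0, g00, diff0 = _base_inputs(genome, frozen)
    elements = [e for kind in MAP_KINDS for e in legal_elements(genome, kind)]
    clouds = []
    if genome.model_kind == "lattice":
        for _ in range(n_samples):
            weights, env, g0, diff = weights0.copy(), env0.copy(), g00.copy(), diff0.copy()
            for element in elements:
                if rng.random() < perturb_probability:
                    _apply_element(weights, env, g0, diff, element, rng.uniform())
            probe = genome.copy()
            probe.interaction_strengths = weights
            probe.topology_mask = np.ones_like(probe.topology_mask)
            probe.diffusion_rates = diff
            probe.initial_state = g0
            result = develop(probe, env, params, rng)
            if result.stable:
                clouds.append(result.traits)
        return np.array(clouds) if clouds else np.empty((0, genome.n_traits))

    weights_batch = np.repeat(weights0[None, :, :], n_samples, axis=0)
    envs = np.repeat(env0[None, :], n_samples, axis=0)
    g0s = np.repeat(g00[None, :], n_samples, axis=0)
    for k in range(n_samples):
        for element in elements:
            if rng.random() < perturb_probability:
                _apply_element(weights_batch[k], envs[k], g0s[k], None, element, rng.uniform())
    finals, earlies = develop_batch(weights_batch, envs, g0s, params, rng)
    for k in range(n_samples):
        if np.isfinite(finals[k]).all() and check_stability(earlies[k], finals[k], params.stability_tol):
            clouds.append(read_phenotype(finals[k], genome, params.trait_genes))
    return np.array(clouds) if clouds else np.empty((0, genome.n_traits))


def build_maps_for_genome(
    genome: GRNGenome,
    env: EnvironmentVector,
    params: DevelopmentParams,
    rng: np.random.Generator,
    grid: np.ndarray | None = None,
    linked_elements: bool = True,
) -> dict[str, PhenotypeMap] | None:
    """Build one GP, EP and PP map with randomly chosen elements.

    By default the three elements are linked to one randomly drawn focal gene
    (:func:`choose_linked_elements`); with ``linked_elements=False`` each map
    kind draws its element independently. Shares a single batched integration
    across the three maps. The genome's own environment freezes the
    non-perturbed inputs. Returns None when the genome has an empty topology
    (no legal GP element).
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    try:
        if linked_elements:
            elements = choose_linked_elements(genome, rng)
        else:
            elements = {kind: choose_element(genome, kind, rng) for kind in MAP_KINDS}
    except ValueError:
        return None
    frozen = FrozenContext(env=env)
    if genome.model_kind == "lattice":
        return {
            kind: build_map(genome, kind, elements[kind], grid, frozen, params, rng)
            for kind in MAP_KINDS
        }
    weights0, env0, g00, _diff0 = _base_inputs(genome, frozen)
    n_grid = len(grid)
    batch = 3 * n_grid
    weights_batch = np.repeat(weights0[None, :, :], batch, axis=0)
    envs = np.repeat(env0[None, :], batch, axis=0)
    g0s = np.repeat(g00[None, :], batch, axis=0)
    for m, kind in enumerate(MAP_KINDS):
        for k, x in enumerate(grid):
            idx = m * n_grid + k
            _apply_element(weights_batch[idx], envs[idx], g0s[idx], None, elements[kind], float(x))
    finals, earlies = develop_batch(weights_batch, envs, g0s, params, rng)
    maps = {}
    for m, kind in enumerate(MAP_KINDS):
        phenotypes = np.full((n_grid, genome.n_traits), np.nan)
        viable = np.zeros(n_grid, dtype=bool)
        for k in range(n_grid):
            idx = m * n_grid + k
            ok = np.isfinite(finals[idx]).all() and check_stability(
                earlies[idx], finals[idx], params.stability_tol
            )
            viable[k] = ok
            if ok:
                phenotypes[k] = read_phenotype(finals[idx], genome, params.trait_genes)
        maps[kind] = PhenotypeMap(kind, elements[kind], grid, phenotypes, viable, genome.genome_id)
    return maps


def draw_collapsed_value(rng: np.random.Generator) -> float:
    """Collapsed input x ~ U(0,1), never exactly 0."""
    x = float(rng.uniform())
    while x == 0.0:
        x = float(rng.uniform())
    return x
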