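"""Control experiments: input/topology randomization and the polynomial null.

The randomization control perturbs GRN topology bits and/or the perturbation
input values with probability ``p_flip`` and correlates the map statistics of
the original and perturbed systems across an ensemble. The polynomial null
samples damped random polynomials ``y(x) = sum_i R_i x^i e^{-i}`` of degree
<= 4 and asks whether map complexities correlate between randomly paired
functions (they should not, unless the pair shares a degree class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from grnmaps.development import DevelopmentParams
from grnmaps.ensemble import EnvironmentVector, GRNGenome
from grnmaps.maps import FrozenContext, build_maps_for_genome
from grnmaps.metrics import map_stats, pearson

POLY_MAX_DEGREE = 4
POLY_GRID = np.arange(1, 11) / 10.0  # x = 0.1, ..., 1.0


@dataclass
class PolynomialMap:
    """A damped random polynomial sampled on the 10-point unit grid."""

    coefficients: np.ndarray  # R(0..4), non-negative
    points: np.ndarray  # (10, 2): (x, y) pairs, y rescaled into [0, 1] if needed

    @property
    def degree(self) -> int:
        nz = np.nonzero(self.coefficients)[0]
        return int(nz[-1]) if len(nz) else 0


def _evaluate_poly(coefficients: np.ndarray, xs: np.ndarray) -> np.ndarray:
    degrees = np.arange(POLY_MAX_DEGREE + 1)
    damped = coefficients * np.exp(-degrees)
    return np.sum(damped[None, :] * xs[:, None] ** degrees[None, :], axis=1)


def random_polynomial(rng: np.random.Generator, degree: int | None = None) -> PolynomialMap:
    """Sample R(i) ~ U(0,1) and evaluate on the 10-point grid.

    With ``degree`` given, coefficients above it are zeroed (and the leading
    one is forced non-zero), stratifying the sample by exact degree class.
    y-values exceeding the unit interval are min-max rescaled into it.
    """
    coeffs = rng.uniform(0.0, 1.0, size=POLY_MAX_DEGREE + 1)
    if degree is not None:
        if not 0 <= degree <= POLY_MAX_DEGREE:
            raise ValueError("degree must be in 0..4")
        coeffs[degree + 1 :] = 0.0
        while coeffs[degree] == 0.0:
            coeffs[degree] = rng.uniform(0.0, 1.0)
    ys = _evaluate_poly(coeffs, POLY_GRID)
    if ys.min() < 0.0 or ys.max() > 1.0:
        span = ys.max() - ys.min()
        ys = (ys - ys.min()) / span if span > 0 else np.zeros_like(ys)
    return PolynomialMap(coefficients=coeffs, points=np.column_stack([POLY_GRID, ys]))


def polynomial_complexity_null(
    n_pairs: int,
    rng: np.random.Generator,
    stratified: bool = True,
) -> dict:
    """Complexity correlation between paired random polynomials.

    Returns Pearson r (complexity machinery shared with the GRN maps) for
    (i) unconstrained pairs and (ii) same-degree pairs, plus the per-degree
    within-stratum complexity spread.
    """
    if n_pairs < 100:
        raise ValueError("polynomial null needs at least 100 pairs")

    def _poly_complexity(pm: PolynomialMap) -> float:
        # a constant polynomial is a perfectly simple (zero-complexity) map;
        # it must not be dropped or the degree-0 class would be empty
        st = map_stats(pm.points)
        return 0.0 if st.degenerate else st.complexity

    def _complexities(sampler) -> tuple[np.ndarray, np.ndarray]:
        ca, cb = [], []
        for _ in range(n_pairs):
            pa, pb = sampler()
            ca.append(_poly_complexity(pa))
            cb.append(_poly_complexity(pb))
        return np.array(ca), np.array(cb)

    ca_free, cb_free = _complexities(lambda: (random_polynomial(rng), random_polynomial(rng)))

    degrees = np.arange(POLY_MAX_DEGREE + 1)

    def _same_degree():
        d = int(rng.choice(degrees)) if stratified else None
        return random_polynomial(rng, degree=d), random_polynomial(rng, degree=d)

    ca_same, cb_same = _complexities(_same_degree)

    per_degree_std = {}
    n_per_degree = max(100, n_pairs // 5)
    for d in degrees:
        cs = [
            _poly_complexity(random_polynomial(rng, degree=int(d)))
            for _ in range(n_per_degree)
        ]
        per_degree_std[int(d)] = float(np.std(cs))
    pooled = np.concatenate([ca_free, cb_free])
    return {
        "r_unconstrained": pearson(ca_free, cb_free),
        "r_same_degree": pearson(ca_same, cb_same),
        "pooled_std": float(np.std(pooled)),
        "per_degree_std": per_degree_std,
    }


def randomize_control(
    pairs: list[tuple[GRNGenome, EnvironmentVector]],
    p_flip: float,
    rng: np.random.Generator,
    params: DevelopmentParams | None = None,
    flip_topology: bool = True,
    randomize_inputs: bool = True,
    grid: np.ndarray | None = None,
) -> dict:
    """Correlate original and perturbed map statistics across an ensemble.

    For each genome: build GP/EP/PP maps; then flip each topology bit with
    probability ``p_flip`` (if ``flip_topology``) and/or redraw each grid
    input value ~ U(0,1) with probability ``p_flip`` (if ``randomize_inputs``)
    and rebuild the maps with the same elements. Returns Pearson r between
    original and perturbed slopes and complexities, pooled over map kinds.
    """
    if not 0.0 <= p_flip <= 1.0:
        raise ValueError("p_flip must be in [0, 1]")
    params = params or DevelopmentParams()
    from grnmaps.maps import build_map, default_grid

    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    s_orig, s_pert, c_orig, c_pert = [], [], [], []
    for genome, env in pairs:
        maps = build_maps_for_genome(genome, env, params, rng, grid=grid)
        if maps is None:
            continue
        perturbed = genome.copy()
        if flip_topology and p_flip > 0:
            flips = rng.random(perturbed.topology_mask.shape) < p_flip
            perturbed.topology_mask = np.where(
                flips, 1 - perturbed.topology_mask, perturbed.topology_mask
            ).astype(np.int8)
        for kind, pmap in maps.items():
            if randomize_inputs and p_flip > 0:
                redraw = rng.random(len(grid)) < p_flip
                new_grid = np.where(redraw, rng.uniform(0.0, 1.0, size=len(grid)), grid)
            else:
                new_grid = grid
            new_map = build_map(
                perturbed,
                kind,
                pmap.perturbed_element,
                new_grid,
                FrozenContext(env=env),
                params,
                rng,
                strict=False,
            )
            st_o = map_stats(pmap)
            st_p = map_stats(new_map)
            if st_o.degenerate or st_p.degenerate:
                continue
            s_orig.append(st_o.transformed_slope)
            s_pert.append(st_p.transformed_slope)
            c_orig.append(st_o.complexity)
            c_pert.append(st_p.complexity)
    result = {
        "p_flip": p_flip,
        "n_maps": len(s_orig),
        "slopes_original": np.array(s_orig),
        "slopes_perturbed": np.array(s_pert),
        "complexities_original": np.array(c_orig),
        "complexities_perturbed": np.array(c_pert),
    }
    try:
        result["r_slope"] = pearson(s_orig, s_pert)
        result["r_complexity"] = pearson(c_orig, c_pert)
    except ValueError:
        result["r_slope"] = float("nan")
        result["r_complexity"] = float("nan")
    return result
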