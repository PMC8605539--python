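"""Developmental dynamics: Euler integration, stability check and trait readout.

Gene concentrations follow saturating (Michaelis-Menten) production driven by
the ramp-rectified regulatory input, linear decay ``mu`` and optional additive
Gaussian noise. The ``basic`` and ``multilinear`` models integrate a single
well-mixed cell; the ``lattice`` model integrates a 1-D row of cells coupled
by morphogen diffusion with zero-flux boundaries.

A developed state is *viable* only if the L1-normalized state changes by at
most ``stability_tol`` (max-norm) between ``0.9 * t_dev`` and ``t_dev``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from grnmaps import _kernels
from grnmaps.ensemble import EnvironmentVector, GRNGenome


@dataclass
class DevelopmentParams:
    """Integration and readout parameters.

    Defaults follow the reference parameterization: ``dt = 1e-3``,
    ``mu = 0.1``, ``K_M = 1``, noise ``N(0, sd=1e-2)``, stability threshold
    ``1e-2`` over a window of ``t_dev / 10``, 16 lattice cells.
    """

    t_dev: float = 100.0
    dt: float = 1e-3
    mu: float = 0.1
    michaelis_km: float = 1.0
    noise_sd: float = 1e-2
    stability_tol: float = 1e-2
    n_cells: int = 16
    noise_enabled: bool = True
    sqrt_dt_noise: bool = False
    trait_genes: tuple[int, int] = (0, 1)

    @property
    def stability_window(self) -> float:
        return self.t_dev / 10.0

    @property
    def n_steps(self) -> int:
        return max(1, int(round(self.t_dev / self.dt)))

    @property
    def checkpoint_step(self) -> int:
        return max(1, int(round(0.9 * self.n_steps)))

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_dev < 10 * self.dt:
            raise ValueError("t_dev must cover at least 10 Euler steps")
        if self.mu <= 0 or self.michaelis_km <= 0:
            raise ValueError("mu and K_M must be positive")
        if self.n_cells < 2:
            raise ValueError("lattice needs at least 2 cells")


@dataclass
class DevelopmentResult:
    """Endpoint of one developmental trajectory."""

    final_state: np.ndarray  # (Ng,) or (Nc, Ng) for the lattice
    stable: bool
    traits: np.ndarray | None
    checkpoint_early: np.ndarray = field(repr=False, default=None)
    checkpoint_final: np.ndarray = field(repr=False, default=None)
    diagnostic: str = ""


def ramp(x: np.ndarray | float) -> np.ndarray | float:
    """R(x) = x for x >= 0, else 0."""
    return np.maximum(x, 0.0)


def regulatory_input(
    state: np.ndarray, genome: GRNGenome, env: EnvironmentVector | np.ndarray
) -> np.ndarray:
    """Total regulatory input ``h_i = sum_j M_ij B_ij g_j + E_i``."""
    state = np.asarray(state, dtype=float)
    env_values = env.values if isinstance(env, EnvironmentVector) else np.asarray(env, dtype=float)
    if state.shape != (genome.n_genes,) or env_values.shape != (genome.n_genes,):
        raise ValueError("state/genome/environment dimensions do not match")
    return genome.effective_weights @ state + env_values


def step_euler(
    state: np.ndarray,
    genome: GRNGenome,
    env: EnvironmentVector | np.ndarray,
    params: DevelopmentParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One synchronous Euler update of a well-mixed state (clamped at 0)."""
    h = regulatory_input(state, genome, env)
    rh = ramp(h)
    production = rh / (params.michaelis_km + rh)
    delta = production - params.mu * np.asarray(state, dtype=float)
    if params.noise_enabled:
        if rng is None:
            raise ValueError("noise enabled but no rng supplied")
        scale = params.noise_sd / np.sqrt(params.dt) if params.sqrt_dt_noise else params.noise_sd
        delta = delta + scale * rng.normal(size=genome.n_genes)
    new_state = state + params.dt * delta
    if not np.isfinite(new_state).all():
        raise FloatingPointError("integration blow-up: non-finite state")
    return np.maximum(new_state, 0.0)


def _laplacian_zero_flux(field_matrix: np.ndarray) -> np.ndarray:
    """Discrete 1-D Laplacian over cells (axis 0) with mirrored ghost cells."""
    padded = np.concatenate([field_matrix[:1], field_matrix, field_matrix[-1:]], axis=0)
    return padded[:-2] + padded[2:] - 2.0 * field_matrix


def step_lattice(
    state_matrix: np.ndarray,
    genome: GRNGenome,
    env: EnvironmentVector | np.ndarray,
    params: DevelopmentParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One Euler update of the Nc x Ng lattice field (reaction + diffusion)."""
    state_matrix = np.asarray(state_matrix, dtype=float)
    env_values = env.values if isinstance(env, EnvironmentVector) else np.asarray(env, dtype=float)
    if state_matrix.ndim != 2 or state_matrix.shape[1] != genome.n_genes:
        raise ValueError("lattice state must be N_c x N_g")
    h = state_matrix @ genome.effective_weights.T + env_values[None, :]
    rh = ramp(h)
    production = rh / (params.michaelis_km + rh)
    diffusion = genome.diffusion_rates[None, :] * _laplacian_zero_flux(state_matrix)
    delta = production - params.mu * state_matrix + diffusion
    if params.noise_enabled:
        if rng is None:
            raise ValueError("noise enabled but no rng supplied")
        scale = params.noise_sd / np.sqrt(params.dt) if params.sqrt_dt_noise else params.noise_sd
        delta = delta + scale * rng.normal(size=state_matrix.shape)
    new_state = state_matrix + params.dt * delta
    if not np.isfinite(new_state).all():
        raise FloatingPointError("integration blow-up: non-finite lattice state")
    return np.maximum(new_state, 0.0)


def _normalize_l1(state: np.ndarray) -> np.ndarray:
    flat = np.asarray(state, dtype=float).ravel()
    total = flat.sum()
    if total <= 0:
        return np.zeros_like(flat)
    return flat / total


def check_stability(
    checkpoint_early: np.ndarray,
    checkpoint_final: np.ndarray,
    tol: float = 1e-2,
) -> bool:
    """Viability: max-norm change of the L1-normalized state within ``tol``."""
    a = _normalize_l1(checkpoint_early)
    b = _normalize_l1(checkpoint_final)
    return bool(np.max(np.abs(a - b)) <= tol)


def read_phenotype(
    final_state: np.ndarray,
    genome: GRNGenome,
    trait_genes: tuple[int, int] = (0, 1),
    stable: bool = True,
) -> np.ndarray:
    """Trait vector from a developed (stable) state.

    basic: steady-state levels of two designated genes; multilinear:
    ``T = Z @ g``; lattice: mean of gene 1 in the first/last two cells.
    """
    if not stable:
        raise ValueError("cannot read the phenotype of an unstable development")
    final_state = np.asarray(final_state, dtype=float)
    if genome.model_kind == "multilinear":
        return genome.multilinear_coeffs @ final_state
    if genome.model_kind == "lattice":
        t1 = 0.5 * (final_state[0, 0] + final_state[1, 0])
        t2 = 0.5 * (final_state[-2, 0] + final_state[-1, 0])
        return np.array([t1, t2])
    return final_state[list(trait_genes)]


def _noise_seed(rng: np.random.Generator | None) -> int:
    if rng is None:
        return 0
    return int(rng.integers(0, 2**31 - 1))


def develop(
    genome: GRNGenome,
    env: EnvironmentVector | np.ndarray,
    params: DevelopmentParams,
    rng: np.random.Generator | None = None,
) -> DevelopmentResult:
    """Integrate the full developmental trajectory and read out the result."""
    env_values = env.values if isinstance(env, EnvironmentVector) else np.asarray(env, dtype=float)
    noise_on = params.noise_enabled
    if noise_on and rng is None:
        raise ValueError("noise enabled but no rng supplied")
    weights = genome.effective_weights
    try:
        if genome.model_kind == "lattice":
            g0 = np.broadcast_to(genome.initial_state, (params.n_cells, genome.n_genes)).copy()
            final, early = _kernels.integrate_lattice(
                weights,
                env_values,
                g0,
                genome.diffusion_rates,
                params.n_steps,
                params.checkpoint_step,
                params.dt,
                params.mu,
                params.michaelis_km,
                params.noise_sd,
                noise_on,
                params.sqrt_dt_noise,
                _noise_seed(rng),
            )
        else:
            finals, earlies = _kernels.integrate_batch(
                weights[None, :, :],
                env_values[None, :],
                genome.initial_state[None, :],
                params.n_steps,
                params.checkpoint_step,
                params.dt,
                params.mu,
                params.michaelis_km,
                params.noise_sd,
                noise_on,
                params.sqrt_dt_noise,
                _noise_seed(rng),
            )
            final, early = finals[0], earlies[0]
    except FloatingPointError as exc:
        return DevelopmentResult(
            final_state=np.full(genome.n_genes, np.nan),
            stable=False,
            traits=None,
            diagnostic=str(exc),
        )
    if not np.isfinite(final).all():
        return DevelopmentResult(final_state=final, stable=False, traits=None, diagnostic="non-finite endpoint")
    stable = check_stability(early, final, params.stability_tol)
    traits = read_phenotype(final, genome, params.trait_genes, stable=True) if stable else None
    return DevelopmentResult(
        final_state=final,
        stable=stable,
        traits=traits,
        checkpoint_early=early,
        checkpoint_final=final,
    )


def reference_develop(
    genome: GRNGenome,
    env: EnvironmentVector | np.ndarray,
    params: DevelopmentParams,
) -> np.ndarray:
    """Noise-free endpoint via an adaptive higher-order integrator (RK45).

    Independent oracle for the Euler path; well-mixed models only.
    """
    from scipy.integrate import solve_ivp

    if genome.model_kind == "lattice":
        raise NotImplementedError("reference integrator covers well-mixed models only")
    env_values = env.values if isinstance(env, EnvironmentVector) else np.asarray(env, dtype=float)
    weights = genome.effective_weights
    mu, km = params.mu, params.michaelis_km

    def rhs(_t, g):
        h = weights @ g + env_values
        rh = np.maximum(h, 0.0)
        return rh / (km + rh) - mu * g

    sol = solve_ivp(
        rhs,
        (0.0, params.t_dev),
        genome.initial_state,
        method="RK45",
        rtol=1e-8,
        atol=1e-10,
    )
    return sol.y[:, -1]


def develop_batch(
    weights: np.ndarray,
    envs: np.ndarray,
    g0s: np.ndarray,
    params: DevelopmentParams,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Low-level batched integration of independent well-mixed systems.

    ``weights``: (batch, Ng, Ng) masked matrices; ``envs``/``g0s``: (batch, Ng).
    Returns (finals, earlies) used by map building and evolution.
    """
    noise_on = params.noise_enabled
    if noise_on and rng is None:
        raise ValueError("noise enabled but no rng supplied")
    return _kernels.integrate_batch(
        np.ascontiguousarray(weights, dtype=float),
        np.ascontiguousarray(envs, dtype=float),
        np.ascontiguousarray(g0s, dtype=float),
        params.n_steps,
        params.checkpoint_step,
        params.dt,
        params.mu,
        params.michaelis_km,
        params.noise_sd,
        noise_on,
        params.sqrt_dt_noise,
        _noise_seed(rng),
    )
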