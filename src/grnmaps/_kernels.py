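"""Numba-compiled inner loops for the Euler integration of GRN dynamics.

All kernels update synchronously from the previous state, clamp
concentrations at zero, and record the state at a checkpoint step (used by
the temporal-stability criterion) as well as at the end of integration.
Noise, when enabled, is an additive Gaussian term inside the Euler update;
the optional ``sqrt_dt`` flag switches to Euler-Maruyama scaling.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def integrate_batch(
    weights,  # (batch, Ng, Ng) masked interaction matrices
    envs,  # (batch, Ng)
    g0s,  # (batch, Ng)
    n_steps,
    checkpoint_step,
    dt,
    mu,
    km,
    noise_sd,
    noise_on,
    sqrt_dt_noise,
    seed,
):
    """Integrate a batch of independent well-mixed GRN systems.

    Returns (finals, checkpoints), each of shape (batch, Ng).
    """
    batch, ng = g0s.shape
    finals = np.zeros((batch, ng))
    checkpoints = np.zeros((batch, ng))
    if noise_on:
        np.random.seed(seed)
    noise_scale = noise_sd / np.sqrt(dt) if sqrt_dt_noise else noise_sd
    for b in range(batch):
        g = g0s[b].copy()
        new_g = np.empty(ng)
        for t in range(n_steps):
            for i in range(ng):
                h = envs[b, i]
                for j in range(ng):
                    h += weights[b, i, j] * g[j]
                if h > 0.0:
                    prod = h / (km + h)
                else:
                    prod = 0.0
                dg = prod - mu * g[i]
                if noise_on:
                    dg += noise_scale * np.random.normal()
                val = g[i] + dt * dg
                new_g[i] = val if val > 0.0 else 0.0
            for i in range(ng):
                g[i] = new_g[i]
            if t + 1 == checkpoint_step:
                for i in range(ng):
                    checkpoints[b, i] = g[i]
        for i in range(ng):
            finals[b, i] = g[i]
    return finals, checkpoints


@njit(cache=False)
def integrate_lattice(
    weights,  # (Ng, Ng)
    env,  # (Ng,)
    g0,  # (Nc, Ng) initial field
    diffusion,  # (Ng,)
    n_steps,
    checkpoint_step,
    dt,
    mu,
    km,
    noise_sd,
    noise_on,
    sqrt_dt_noise,
    seed,
):
    """Integrate one lattice system: Nc cells sharing a GRN, zero-flux diffusion.

    Returns (final, checkpoint), each (Nc, Ng).
    """
    nc, ng = g0.shape
    final = np.zeros((nc, ng))
    checkpoint = np.zeros((nc, ng))
    if noise_on:
        np.random.seed(seed)
    noise_scale = noise_sd / np.sqrt(dt) if sqrt_dt_noise else noise_sd
    g = g0.copy()
    new_g = np.empty((nc, ng))
    for t in range(n_steps):
        for c in range(nc):
            # mirrored ghost cells: zero-flux boundary
            left = c - 1 if c > 0 else 0
            right = c + 1 if c < nc - 1 else nc - 1
            for i in range(ng):
                h = env[i]
                for j in range(ng):
                    h += weights[i, j] * g[c, j]
                if h > 0.0:
                    prod = h / (km + h)
                else:
                    prod = 0.0
                lap = g[left, i] + g[right, i] - 2.0 * g[c, i]
                dg = prod - mu * g[c, i] + diffusion[i] * lap
                if noise_on:
                    dg += noise_scale * np.random.normal()
                val = g[c, i] + dt * dg
                new_g[c, i] = val if val > 0.0 else 0.0
        for c in range(nc):
            for i in range(ng):
                g[c, i] = new_g[c, i]
        if t + 1 == checkpoint_step:
            for c in range(nc):
                for i in range(ng):
                    checkpoint[c, i] = g[c, i]
    for c in range(nc):
        for i in range(ng):
            final[c, i] = g[c, i]
    return final, checkpoint
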