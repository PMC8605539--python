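import numpy as np
import pytest

from grnmaps.development import DevelopmentParams
from grnmaps.ensemble import EnsembleConfig, GRNGenome, build_ensemble


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_params():
    """Desk-scale deterministic integration used throughout the unit tests."""
    return DevelopmentParams(t_dev=20.0, dt=1e-2, noise_enabled=False)


@pytest.fixture
def long_params():
    """Long enough to equilibrate slow systems; still noise-free."""
    return DevelopmentParams(t_dev=200.0, dt=1e-2, noise_enabled=False)


def make_genome(
    n_genes=3,
    mask=None,
    strengths=None,
    g0=None,
    model_kind="basic",
    z=None,
    d=None,
):
    mask = np.zeros((n_genes, n_genes), dtype=np.int8) if mask is None else np.asarray(mask, dtype=np.int8)
    strengths = np.zeros((n_genes, n_genes)) if strengths is None else np.asarray(strengths, dtype=float)
    g0 = np.full(n_genes, 0.5) if g0 is None else np.asarray(g0, dtype=float)
    return GRNGenome(
        n_genes=n_genes,
        topology_mask=mask,
        interaction_strengths=strengths,
        initial_state=g0,
        model_kind=model_kind,
        multilinear_coeffs=None if z is None else np.asarray(z, dtype=float),
        diffusion_rates=None if d is None else np.asarray(d, dtype=float),
    )


@pytest.fixture
def self_activator():
    """Self-activating gene 0 with B=2 (gene 1 inert): steady state g0* = 9.5."""
    return make_genome(
        n_genes=2,
        mask=[[1, 0], [0, 0]],
        strengths=[[2.0, 0.0], [0.0, 0.0]],
        g0=[0.5, 0.0],
    )


@pytest.fixture
def small_ensemble():
    return build_ensemble(EnsembleConfig(n_networks=30, seed=7, ng_max=8))
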