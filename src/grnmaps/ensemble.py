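"""Random generation of GRN genomes and environmental inputs.

Sampling scheme for the random ensemble: network size ``N_g ~ U{3..24}``,
per-network connection probability ``c ~ U(0,1)`` with each topology entry
``M_ij = 1`` with probability ``c``, interaction strengths ``B_ij ~ N(0,1)``
where the topology allows them, initial state ``G0 ~ U(0,1)``, multilinear
trait coefficients ``Z ~ U(-1,1)`` and morphogen diffusion rates
``D ~ U(0,1)``. Environmental inputs are exponential, ``E_i ~ Exp(1)``,
clipped to the admissible upper bound of 1.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

MODEL_KINDS = ("basic", "multilinear", "lattice")

NG_MIN_DEFAULT = 3
NG_MAX_DEFAULT = 24


def n_diffusible(n_genes: int) -> int:
    """Number of diffusible morphogen genes in the lattice model (first third)."""
    return math.ceil(n_genes / 3)


@dataclass
class GRNGenome:
    """All heritable / parametric state of one developmental system.

    Attributes
    ----------
    n_genes:
        Network size ``N_g``.
    topology_mask:
        Binary ``N_g x N_g`` matrix; an interaction is active only where 1.
    interaction_strengths:
        Real ``N_g x N_g`` matrix of regulatory effects (column gene acts on
        row gene). Effective only where the topology mask is 1.
    initial_state:
        Non-negative initial concentrations (the parentally provided state).
    multilinear_coeffs:
        ``N_t x N_g`` trait-contribution matrix (multilinear model), else None.
    diffusion_rates:
        Length-``N_g`` diffusion rates, non-zero only for the first
        ``ceil(N_g/3)`` genes (lattice model), else None.
    model_kind:
        One of ``basic``, ``multilinear``, ``lattice``.
    """

    n_genes: int
    topology_mask: np.ndarray
    interaction_strengths: np.ndarray
    initial_state: np.ndarray
    model_kind: str = "basic"
    multilinear_coeffs: np.ndarray | None = None
    diffusion_rates: np.ndarray | None = None
    genome_id: int | None = None

    def __post_init__(self) -> None:
        self.topology_mask = np.asarray(self.topology_mask, dtype=np.int8)
        self.interaction_strengths = np.asarray(self.interaction_strengths, dtype=float)
        self.initial_state = np.asarray(self.initial_state, dtype=float)
        if self.multilinear_coeffs is not None:
            self.multilinear_coeffs = np.asarray(self.multilinear_coeffs, dtype=float)
        if self.diffusion_rates is not None:
            self.diffusion_rates = np.asarray(self.diffusion_rates, dtype=float)

    def validate(self) -> None:
        n = self.n_genes
        if not NG_MIN_DEFAULT <= n <= NG_MAX_DEFAULT:
            raise ValueError(f"n_genes={n} outside [{NG_MIN_DEFAULT}, {NG_MAX_DEFAULT}]")
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.topology_mask.shape != (n, n):
            raise ValueError("topology mask shape mismatch")
        if not np.isin(self.topology_mask, (0, 1)).all():
            raise ValueError("topology mask must be binary")
        if self.interaction_strengths.shape != (n, n):
            raise ValueError("interaction matrix shape mismatch")
        if self.initial_state.shape != (n,) or (self.initial_state < 0).any():
            raise ValueError("initial state must be length N_g and non-negative")
        if self.model_kind == "multilinear":
            if self.multilinear_coeffs is None or self.multilinear_coeffs.shape[1] != n:
                raise ValueError("multilinear model requires an N_t x N_g coefficient matrix")
            if (np.abs(self.multilinear_coeffs) >= 1).any():
                raise ValueError("multilinear coefficients must lie in (-1, 1)")
        if self.model_kind == "lattice":
            if self.diffusion_rates is None or self.diffusion_rates.shape != (n,):
                raise ValueError("lattice model requires a length-N_g diffusion vector")
            k = n_diffusible(n)
            d = self.diffusion_rates
            if (d[:k] <= 0).any() or (d[:k] >= 1).any() or (d[k:] != 0).any():
                raise ValueError("diffusion rates must be in (0,1) for the first ceil(N_g/3) genes and 0 elsewhere")

    @property
    def effective_weights(self) -> np.ndarray:
        """Masked interaction matrix ``M * B`` actually driving the dynamics."""
        return self.topology_mask * self.interaction_strengths

    @property
    def n_traits(self) -> int:
        if self.multilinear_coeffs is not None:
            return self.multilinear_coeffs.shape[0]
        return 2

    def copy(self) -> "GRNGenome":
        return GRNGenome(
            n_genes=self.n_genes,
            topology_mask=self.topology_mask.copy(),
            interaction_strengths=self.interaction_strengths.copy(),
            initial_state=self.initial_state.copy(),
            model_kind=self.model_kind,
            multilinear_coeffs=None if self.multilinear_coeffs is None else self.multilinear_coeffs.copy(),
            diffusion_rates=None if self.diffusion_rates is None else self.diffusion_rates.copy(),
            genome_id=self.genome_id,
        )


@dataclass
class EnvironmentVector:
    """Per-gene environmental modulation values in [-1, 1].

    ``raw_values`` keeps the pre-clip exponential draws for diagnostics.
    """

    values: np.ndarray
    raw_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.raw_values is not None:
            self.raw_values = np.asarray(self.raw_values, dtype=float)

    def validate(self, n_genes: int | None = None) -> None:
        if n_genes is not None and self.values.shape != (n_genes,):
            raise ValueError("environment length must equal N_g")
        if (np.abs(self.values) > 1).any():
            raise ValueError("environment entries must lie in [-1, 1]")

    def copy(self) -> "EnvironmentVector":
        return EnvironmentVector(
            self.values.copy(),
            None if self.raw_values is None else self.raw_values.copy(),
        )


@dataclass
class EnsembleConfig:
    """Configuration of a random-ensemble draw."""

    n_networks: int
    model_kind: str = "multilinear"
    seed: int = 0
    n_traits: int = 2
    ng_min: int = NG_MIN_DEFAULT
    ng_max: int = NG_MAX_DEFAULT
    connectivity: float | None = None  # None: per-network c ~ U(0,1)
    random_env_sign: bool = False

    def validate(self) -> None:
        if self.n_networks < 0:
            raise ValueError("n_networks must be >= 0")
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if not (NG_MIN_DEFAULT <= self.ng_min <= self.ng_max <= NG_MAX_DEFAULT):
            raise ValueError("N_g range must satisfy 3 <= ng_min <= ng_max <= 24")
        if self.model_kind == "multilinear" and self.n_traits >= self.ng_min:
            raise ValueError("multi-trait runs require N_g > N_t for every genome")
        if self.connectivity is not None and not 0.0 <= self.connectivity <= 1.0:
            raise ValueError("connectivity must be in [0, 1]")

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def sample_grn(config: EnsembleConfig, rng: np.random.Generator) -> GRNGenome:
    """Draw one random genome under the ensemble sampling scheme."""
    n = int(rng.integers(config.ng_min, config.ng_max + 1))
    c = config.connectivity if config.connectivity is not None else rng.uniform()
    mask = (rng.random((n, n)) < c).astype(np.int8)
    strengths = rng.normal(0.0, 1.0, size=(n, n))
    g0 = rng.uniform(0.0, 1.0, size=n)
    z = None
    d = None
    if config.model_kind == "multilinear":
        z = rng.uniform(-1.0, 1.0, size=(config.n_traits, n))
    elif config.model_kind == "lattice":
        d = np.zeros(n)
        k = n_diffusible(n)
        d[:k] = rng.uniform(0.0, 1.0, size=k)
        # open-interval bound: resample the (measure-zero) exact endpoints
        while ((d[:k] <= 0) | (d[:k] >= 1)).any():
            bad = (d[:k] <= 0) | (d[:k] >= 1)
            d[:k][bad] = rng.uniform(0.0, 1.0, size=int(bad.sum()))
    return GRNGenome(
        n_genes=n,
        topology_mask=mask,
        interaction_strengths=strengths,
        initial_state=g0,
        model_kind=config.model_kind,
        multilinear_coeffs=z,
        diffusion_rates=d,
    )


def sample_environment(
    genome: GRNGenome,
    rng: np.random.Generator,
    random_sign: bool = False,
) -> EnvironmentVector:
    """Draw a per-gene environment: magnitude ~ Exp(1), clipped at 1.

    With ``random_sign`` each entry's sign is flipped independently with
    probability 1/2; by default all entries are (weakly) up-regulating.
    """
    raw = rng.exponential(1.0, size=genome.n_genes)
    values = np.minimum(raw, 1.0)
    if random_sign:
        values = values * rng.choice((-1.0, 1.0), size=genome.n_genes)
    return EnvironmentVector(values=values, raw_values=raw)


def build_ensemble(
    config: EnsembleConfig,
    archive_path: str | Path | None = None,
) -> list[tuple[GRNGenome, EnvironmentVector]]:
    """Deterministically generate ``n_networks`` (genome, environment) pairs.

    When ``archive_path`` is given the ensemble is persisted to an HDF5
    container with a JSON sidecar (config + seed) and a CSV manifest.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pairs: list[tuple[GRNGenome, EnvironmentVector]] = []
    for i in range(config.n_networks):
        genome = sample_grn(config, rng)
        genome.genome_id = i
        env = sample_environment(genome, rng, random_sign=config.random_env_sign)
        pairs.append((genome, env))
    if archive_path is not None:
        try:
            save_ensemble(pairs, config, archive_path)
        except OSError as exc:  # sampling succeeded; persistence did not
            raise EnsembleIOError(f"failed to persist ensemble to {archive_path}: {exc}") from exc
    return pairs


class EnsembleIOError(IOError):
    """Raised when persisting or loading an ensemble archive fails."""


def save_ensemble(
    pairs: list[tuple[GRNGenome, EnvironmentVector]],
    config: EnsembleConfig,
    archive_path: str | Path,
) -> None:
    import h5py

    archive_path = Path(archive_path)
    archive_path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(archive_path, "w") as fh:
        fh.attrs["seed"] = config.seed
        fh.attrs["config_hash"] = config.content_hash()
        fh.attrs["config_json"] = json.dumps(asdict(config), sort_keys=True)
        for genome, env in pairs:
            grp = fh.create_group(f"genome_{genome.genome_id:06d}")
            grp.attrs["model_kind"] = genome.model_kind
            grp.attrs["n_genes"] = genome.n_genes
            grp.create_dataset("M", data=genome.topology_mask)
            grp.create_dataset("B", data=genome.interaction_strengths)
            grp.create_dataset("G0", data=genome.initial_state)
            grp.create_dataset("E", data=env.values)
            if env.raw_values is not None:
                grp.create_dataset("E_raw", data=env.raw_values)
            if genome.multilinear_coeffs is not None:
                grp.create_dataset("Z", data=genome.multilinear_coeffs)
            if genome.diffusion_rates is not None:
                grp.create_dataset("D", data=genome.diffusion_rates)
    sidecar = archive_path.with_suffix(archive_path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"seed": config.seed, "config": asdict(config), "config_hash": config.content_hash()}, indent=2)
    )
    manifest = archive_path.with_suffix(".manifest.csv")
    with manifest.open("w") as fh:
        fh.write("genome_id,n_genes,connectivity,model_kind\n")
        for genome, _env in pairs:
            conn = float(genome.topology_mask.mean()) if genome.n_genes else 0.0
            fh.write(f"{genome.genome_id},{genome.n_genes},{conn:.6f},{genome.model_kind}\n")


def load_ensemble(archive_path: str | Path) -> tuple[list[tuple[GRNGenome, EnvironmentVector]], dict]:
    import h5py

    archive_path = Path(archive_path)
    if not archive_path.exists():
        raise EnsembleIOError(f"no such archive: {archive_path}")
    pairs = []
    with h5py.File(archive_path, "r") as fh:
        meta = {"seed": int(fh.attrs["seed"]), "config_hash": str(fh.attrs["config_hash"])}
        for name in sorted(fh.keys()):
            grp = fh[name]
            genome = GRNGenome(
                n_genes=int(grp.attrs["n_genes"]),
                topology_mask=grp["M"][()],
                interaction_strengths=grp["B"][()],
                initial_state=grp["G0"][()],
                model_kind=str(grp.attrs["model_kind"]),
                multilinear_coeffs=grp["Z"][()] if "Z" in grp else None,
                diffusion_rates=grp["D"][()] if "D" in grp else None,
                genome_id=int(name.split("_")[1]),
            )
            env = EnvironmentVector(
                values=grp["E"][()],
                raw_values=grp["E_raw"][()] if "E_raw" in grp else None,
            )
            pairs.append((genome, env))
    return pairs, meta
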