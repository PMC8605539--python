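"""End-to-end experiment drivers: ensemble map correlations, evolution,
grain sweeps, controls and multi-trait comparisons.

Each driver consumes an :class:`ExperimentSpec`, writes plain CSV tables plus
a JSON sidecar (config echo, seed, config hash) to the output directory, and
returns its summary as a dict of dataframes / scalars for programmatic use.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from grnmaps.controls import polynomial_complexity_null, randomize_control
from grnmaps.development import DevelopmentParams
from grnmaps.ensemble import EnsembleConfig, build_ensemble
from grnmaps.evolution import (
    EvolutionConfig,
    evaluate_individual,
    evolve,
    init_population,
    probe_nonselected_maps,
)
from grnmaps.maps import MAP_KINDS, build_maps_for_genome, default_grid, sample_gpd
from grnmaps.metrics import (
    averaged_slope,
    classify_pair,
    composite_slope,
    euclidean_distance,
    map_stats,
    pearson,
)

logger = logging.getLogger("grnmaps")

EXPERIMENTS = (
    "map_correlations",
    "evolve_single_map",
    "shifting_target",
    "grain_sweep",
    "controls",
    "multitrait",
)


@dataclass
class ExperimentSpec:
    experiment: str
    seed: int
    outdir: str | Path | None = None
    replicates: int = 30
    ensemble: EnsembleConfig = field(default_factory=lambda: EnsembleConfig(n_networks=1000))
    evolution: EvolutionConfig = field(default_factory=EvolutionConfig)
    dev_params: DevelopmentParams = field(default_factory=DevelopmentParams)
    grain_grid: tuple[float, ...] = (0.25, 1.0, 10.0)
    p_flip_grid: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))
    n_gpd_samples: int = 200
    grid_points: int = 11

    def validate(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.ensemble.validate()
        self.evolution.validate()

    def sidecar(self) -> dict:
        def _clean(obj):
            if isinstance(obj, dict):
                return {str(k): _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return _clean(asdict(self))


def _write_outputs(spec: ExperimentSpec, tables: dict[str, pd.DataFrame], summary: dict) -> None:
    if spec.outdir is None:
        return
    outdir = Path(spec.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    sidecar = {"spec": spec.sidecar(), "summary": _jsonable(summary)}
    (outdir / f"{spec.experiment}_summary.json").write_text(json.dumps(sidecar, indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.generic,)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def ensemble_map_table(
    spec: ExperimentSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Build GP/EP/PP maps for every ensemble genome; one row per (genome, kind).

    Elements are re-randomized per genome. Failures and degenerate maps are
    isolated per genome and flagged, never aborting the sweep.
    """
    rng = rng or np.random.default_rng(spec.seed)
    pairs = build_ensemble(spec.ensemble)
    grid = default_grid(spec.grid_points)
    rows = []
    for genome, env in pairs:
        try:
            maps = build_maps_for_genome(genome, env, spec.dev_params, rng, grid=grid)
        except Exception as exc:  # pragma: no cover - defensive isolation
            logger.error("genome %s failed: %s", genome.genome_id, exc)
            continue
        if maps is None:
            logger.warning("genome %s has no legal GP element", genome.genome_id)
            continue
        ed = {}
        for a in MAP_KINDS:
            for b in MAP_KINDS:
                if a < b:
                    pa, pb = maps[a], maps[b]
                    both = pa.viable_flags & pb.viable_flags
                    ed[f"ED_raw_{a}_{b}"] = np.nan
                    ed[f"ED_{a}_{b}"] = np.nan
                    if both.sum() >= 1:
                        pts_a = pa.phenotypes[both]
                        pts_b = pb.phenotypes[both]
                        ed[f"ED_raw_{a}_{b}"] = euclidean_distance(pts_a, pts_b)
                        # size-effect-free ED: both maps rescaled into a common unit box
                        stacked = np.vstack([pts_a, pts_b])
                        lo, hi = stacked.min(axis=0), stacked.max(axis=0)
                        span = hi - lo
                        if (span > 0).all():
                            ed[f"ED_{a}_{b}"] = euclidean_distance(
                                (pts_a - lo) / span, (pts_b - lo) / span
                            )
        for kind, pmap in maps.items():
            st = map_stats(pmap)
            rows.append(
                {
                    "genome_id": genome.genome_id,
                    "n_genes": genome.n_genes,
                    "map_kind": kind,
                    "element": f"{pmap.perturbed_element.kind}:{pmap.perturbed_element.i}:{pmap.perturbed_element.j}",
                    "n_viable": int(pmap.viable_flags.sum()),
                    "degenerate": st.degenerate,
                    "slope": st.raw_slope,
                    "transformed_slope": st.transformed_slope,
                    "complexity": st.complexity,
                    **ed,
                }
            )
    return pd.DataFrame(rows)


def correlation_summary(table: pd.DataFrame) -> dict:
    """Pairwise slope/complexity correlations and sector frequencies."""
    wide_s = table.pivot(index="genome_id", columns="map_kind", values="transformed_slope")
    wide_c = table.pivot(index="genome_id", columns="map_kind", values="complexity")
    out = {"slope_r": {}, "complexity_r": {}, "sectors": {}, "n_genomes": int(wide_s.shape[0])}
    for a, b in (("GP", "EP"), ("GP", "PP"), ("EP", "PP")):
        sub = wide_s[[a, b]].dropna()
        try:
            out["slope_r"][f"{a}-{b}"] = pearson(sub[a], sub[b])
        except ValueError:
            out["slope_r"][f"{a}-{b}"] = float("nan")
        subc = wide_c[[a, b]].dropna()
        try:
            out["complexity_r"][f"{a}-{b}"] = pearson(subc[a], subc[b])
        except ValueError:
            out["complexity_r"][f"{a}-{b}"] = float("nan")
        labels = [classify_pair(sa, sb).label for sa, sb in zip(sub[a], sub[b])]
        counts = pd.Series(labels).value_counts(normalize=True).to_dict() if labels else {}
        out["sectors"][f"{a}-{b}"] = counts
    # pooled complexity concordance over all three map pairs (one scatter)
    pooled_a, pooled_b = [], []
    for a, b in (("GP", "EP"), ("GP", "PP"), ("EP", "PP")):
        subc = wide_c[[a, b]].dropna()
        pooled_a.append(subc[a].to_numpy())
        pooled_b.append(subc[b].to_numpy())
    pooled_a = np.concatenate(pooled_a)
    pooled_b = np.concatenate(pooled_b)
    try:
        out["complexity_r_pooled"] = pearson(pooled_a, pooled_b)
    except ValueError:
        out["complexity_r_pooled"] = float("nan")
    ed_cols = [c for c in table.columns if c.startswith("ED_") and not c.startswith("ED_raw")]
    pooled = table.loc[table["map_kind"] == "GP", ed_cols].to_numpy().ravel()
    pooled = pooled[np.isfinite(pooled)]
    if len(pooled):
        edges = np.arange(0.0, max(pooled.max(), 0.5) + 0.5, 0.5)
        hist, _ = np.histogram(pooled, bins=edges)
        out["ed_mode"] = float(edges[np.argmax(hist)] + 0.25)
        out["ed_median"] = float(np.median(pooled))
    return out


def run_map_correlations(spec: ExperimentSpec) -> dict:
    """Ensemble sweep: maps, slope/complexity correlations, sectors, ED, GPD."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    table = ensemble_map_table(spec, rng)
    summary = correlation_summary(table)
    # a small GPD sample for the first few genomes (containment diagnostics)
    gpd_rows = []
    pairs = build_ensemble(spec.ensemble)
    for genome, env in pairs[: min(5, len(pairs))]:
        from grnmaps.maps import FrozenContext

        cloud = sample_gpd(
            genome, spec.n_gpd_samples, spec.dev_params, rng, frozen=FrozenContext(env=env)
        )
        for sid, row in enumerate(cloud):
            gpd_rows.append({"genome_id": genome.genome_id, "sample_id": sid, "T1": row[0], "T2": row[1]})
    tables = {"map_table": table, "gpd_samples": pd.DataFrame(gpd_rows)}
    _write_outputs(spec, tables, summary)
    return {"summary": summary, "tables": tables}


def run_evolution_experiments(spec: ExperimentSpec) -> dict:
    """Replicated evolution of a single selected map, with post-hoc probes."""
    spec.validate()
    master = np.random.default_rng(spec.seed)
    pairs = build_ensemble(spec.ensemble)
    run_rows, probe_rows = [], []
    for rep in range(spec.replicates):
        rep_seed = int(master.integers(2**31 - 1))
        rng = np.random.default_rng(rep_seed)
        config = spec.evolution
        population = init_population(pairs, config, rng)
        run = evolve(population, config, rng, seed=rep_seed, replicate_id=rep)
        for rec in run.records():
            run_rows.append({"replicate": rep, "seed": rep_seed, **rec})
        probes = probe_nonselected_maps(run.final_population, config, rng, n_collapsed=2)
        for kind, records in probes.items():
            for rec in records:
                probe_rows.append(
                    {
                        "replicate": rep,
                        "map_kind": kind,
                        "individual": rec["individual"],
                        "collapsed_x": rec["collapsed_x"],
                        "slope": rec["slope"],
                        "transformed_slope": rec["transformed_slope"],
                        "selected_slope": rec["selected_slope"],
                        "selected_transformed_slope": rec["selected_transformed_slope"],
                    }
                )
    runs = pd.DataFrame(run_rows)
    probes_df = pd.DataFrame(probe_rows)
    summary = {"selected_map": spec.evolution.selected_map_kind, "probe_r": {}}
    for kind in MAP_KINDS:
        sub = probes_df[(probes_df["map_kind"] == kind)].dropna(
            subset=["transformed_slope", "selected_transformed_slope"]
        )
        if len(sub) >= 3:
            try:
                summary["probe_r"][kind] = pearson(
                    sub["transformed_slope"], sub["selected_transformed_slope"]
                )
            except ValueError:
                summary["probe_r"][kind] = float("nan")
    tables = {"evolution_runs": runs, "probe_maps": probes_df}
    _write_outputs(spec, tables, summary)
    return {"summary": summary, "tables": tables}


def run_grain_sweep(spec: ExperimentSpec) -> dict:
    """Terminal ED-based fitness as a function of selective grain."""
    spec.validate()
    master = np.random.default_rng(spec.seed)
    pairs = build_ensemble(spec.ensemble)
    rows = []
    from dataclasses import replace as _replace

    for grain in spec.grain_grid:
        for rep in range(spec.replicates):
            rep_seed = int(master.integers(2**31 - 1))
            rng = np.random.default_rng(rep_seed)
            config = _replace(spec.evolution, grain=float(grain), fitness_mode="euclidean")
            population = init_population(pairs, config, rng)
            run = evolve(population, config, rng, seed=rep_seed, replicate_id=rep)
            # terminal fitness measured on the full standard grid
            full_grid = default_grid(spec.grid_points)
            terminal = [
                evaluate_individual(ind, config, full_grid, rng)[0] for ind in run.final_population
            ]
            rows.append(
                {
                    "grain": grain,
                    "replicate": rep,
                    "seed": rep_seed,
                    "terminal_mean_W": float(np.mean(terminal)),
                    "converged_at": run.converged_at,
                }
            )
    table = pd.DataFrame(rows)
    summary = {
        "mean_terminal_by_grain": table.groupby("grain")["terminal_mean_W"].mean().to_dict()
    }
    _write_outputs(spec, {"grain_sweep": table}, summary)
    return {"summary": summary, "tables": {"grain_sweep": table}}


def run_controls(spec: ExperimentSpec) -> dict:
    """Topology/input randomization sweep plus the polynomial complexity null."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pairs = build_ensemble(spec.ensemble)
    rows = []
    for p_flip in spec.p_flip_grid:
        res_topo = randomize_control(
            pairs, float(p_flip), rng, spec.dev_params, flip_topology=True, randomize_inputs=False
        )
        res_inputs = randomize_control(
            pairs, float(p_flip), rng, spec.dev_params, flip_topology=False, randomize_inputs=True
        )
        rows.append(
            {
                "p_flip": p_flip,
                "r_slope_topology": res_topo["r_slope"],
                "r_complexity_topology": res_topo["r_complexity"],
                "r_slope_inputs": res_inputs["r_slope"],
                "r_complexity_inputs": res_inputs["r_complexity"],
            }
        )
    null = polynomial_complexity_null(max(100, spec.ensemble.n_networks), rng)
    table = pd.DataFrame(rows)
    summary = {
        "polynomial_null": {
            "r_unconstrained": null["r_unconstrained"],
            "r_same_degree": null["r_same_degree"],
        }
    }
    _write_outputs(spec, {"randomization_controls": table}, summary)
    return {"summary": summary, "tables": {"randomization_controls": table}}


def run_multitrait(spec: ExperimentSpec) -> dict:
    """Map correlations for N_t > 2 via the three multi-trait methods."""
    spec.validate()
    if spec.ensemble.n_traits <= 2:
        raise ValueError("multitrait experiment needs n_traits > 2")
    rng = np.random.default_rng(spec.seed)
    pairs = build_ensemble(spec.ensemble)
    grid = default_grid(spec.grid_points)
    rows = []
    for genome, env in pairs:
        maps = build_maps_for_genome(genome, env, spec.dev_params, rng, grid=grid)
        if maps is None:
            continue
        rec = {"genome_id": genome.genome_id}
        ok = True
        for kind, pmap in maps.items():
            pts = pmap.viable_points()
            if len(pts) < 2:
                ok = False
                break
            try:
                rec[f"composite_{kind}"] = composite_slope(pts)
                rec[f"averaged_{kind}"] = averaged_slope(pts)
            except ValueError:
                ok = False
                break
        if ok:
            rows.append(rec)
    table = pd.DataFrame(rows)
    summary = {"method_r": {}}
    for method in ("composite", "averaged"):
        for a, b in (("GP", "EP"), ("GP", "PP"), ("EP", "PP")):
            cols = table[[f"{method}_{a}", f"{method}_{b}"]].dropna()
            if len(cols) >= 3:
                try:
                    summary["method_r"][f"{method}:{a}-{b}"] = pearson(
                        cols.iloc[:, 0], cols.iloc[:, 1]
                    )
                except ValueError:
                    summary["method_r"][f"{method}:{a}-{b}"] = float("nan")
    _write_outputs(spec, {"multitrait_slopes": table}, summary)
    return {"summary": summary, "tables": {"multitrait_slopes": table}}


RUNNERS = {
    "map_correlations": run_map_correlations,
    "evolve_single_map": run_evolution_experiments,
    "shifting_target": run_evolution_experiments,
    "grain_sweep": run_grain_sweep,
    "controls": run_controls,
    "multitrait": run_multitrait,
}


def run_experiment(spec: ExperimentSpec) -> dict:
    spec.validate()
    return RUNNERS[spec.experiment](spec)
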