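"""Write a complete synthetic study scenario to disk.

Bundles the generators in :mod:`snakemaps.synthetic` into a ready-to-run
input set — environmental rasters for current and future climates,
biased occurrence records for every species plus a target-group pool,
a population raster, expert-style range polygons, and a pipeline config
— together with a manifest recording the seeds and true niche
parameters, so every downstream result can be checked against the
known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as gio
from . import synthetic as syn
from .grid import GridSpec
from .pipeline import Params, PipelineConfig


@dataclass
class ScenarioSpec:
    """Shape of the synthetic study system.

    Defaults describe a desk-scale landscape: a 120x120 cell window at
    0.01 degrees near the equator, six autocorrelated environmental
    layers of which the first two are a designed collinear pair and the
    first and third are "climate" (they shift in the future steps), two
    modelling units — one with two pooled species, one single-species —
    and a seventh of the points coming from a biased target-group pool.
    """

    n_rows: int = 120
    n_cols: int = 120
    origin_lon: float = 10.0
    origin_lat: float = 1.0
    cell_size: float = 0.01
    n_layers: int = 6
    corr_pairs: tuple = ((0, 1),)
    climate_layers: tuple = (0, 2)
    # mean shift of each climate layer per future step (sd units)
    deltas: dict = field(
        default_factory=lambda: {"2050": {0: 0.5, 2: 0.3}, "2090": {0: 1.0, 2: 0.6}}
    )
    n_gcms: int = 7
    gcm_noise_sd: float = 0.1
    mus: dict = field(
        default_factory=lambda: {"mu1": ["sp_a", "sp_b"], "mu2": ["sp_c"]}
    )
    n_per_species: int = 150
    n_target_group: int = 800
    edr_cutoff: float = 0.5
    pop_clusters: int = 10

    def grid_spec(self) -> GridSpec:
        return GridSpec(
            self.origin_lon, self.origin_lat, self.n_rows, self.n_cols, self.cell_size
        )


#: truth coefficients used by the parameter-recovery harness: a niche
#: concentrated on ~15% of the landscape (two climate drivers, one with a
#: quadratic optimum), typical of a range-restricted species.
RECOVERY_LINEAR = (5.0, 0.0, 3.0, 0.0, 0.0, 0.0)
RECOVERY_QUADRATIC = (-2.0, 0.0, 0.0, 0.0, 0.0, 0.0)
RECOVERY_INTERCEPT = -4.0


def parameter_recovery(
    seed: int = 0,
    n_rows: int = 200,
    n_cols: int = 200,
    n_presence: int = 200,
    n_pool: int = 4000,
    n_held_out: int = 200,
    params: Params | None = None,
) -> dict:
    """Run the modelling chain on generated data with known truth.

    Builds a six-layer landscape (one designed collinear pair), samples
    presences proportional to a known logistic suitability surface times
    a road-like sampling-bias field, forms a target-group background
    from a bias-only point pool, then runs collinearity screening, the
    cross-validated starting model with permutation importances,
    variable reduction, and the full model projected back to the
    landscape.  Returns the Spearman correlation of the prediction with
    the truth surface and the AUC on an independent, unbiased held-out
    presence sample against random landscape cells.
    """
    from scipy.stats import spearmanr

    from . import enm, predictors
    from .grid import Grid
    from .validation import auc

    p = params or Params()
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 7, size=6)
    spec = GridSpec(0.0, 2.0, n_rows, n_cols)
    stack_grids = syn.gen_env_stack(spec, 6, [(0, 1)], seed=int(sub[0]))
    truth = syn.TruthModel(
        np.array(RECOVERY_LINEAR), np.array(RECOVERY_QUADRATIC), RECOVERY_INTERCEPT
    )
    truth_grid = syn.gen_true_suitability(stack_grids, truth)
    bias = syn.gen_bias_field(spec, "gradient", seed=int(sub[1]))
    occ = syn.gen_occurrences(truth_grid, n_presence, bias, seed=int(sub[2]))
    stack = {f"env{k:02d}": g for k, g in enumerate(stack_grids)}
    pres = enm.extract_values(stack, occ.cells(spec))
    flat = Grid(spec, np.ones(spec.shape))
    pool = syn.gen_occurrences(flat, n_pool, bias, seed=int(sub[3]))
    bg_X = enm.extract_values(stack, np.unique(pool.cells(spec), axis=0))

    kept = predictors.collinearity_filter(bg_X, p.r_max)
    cv_aucs, importances = enm.cv_with_importance(
        pres[kept], bg_X[kept], k=p.cv_k, train_frac=p.train_frac,
        seed=int(sub[4]), n_perm=p.n_perm, beta=p.beta,
    )
    reduced = predictors.reduce_variables(
        importances, n_presence, p.top_k, p.pi_min, p.rank_divisor
    )
    model = enm.fit_model(pres[reduced], bg_X[reduced], beta=p.beta)
    pred = enm.predict(model, stack)
    rho = float(
        spearmanr(pred.values.ravel(), truth_grid.values.ravel()).statistic
    )
    held = syn.gen_occurrences(truth_grid, n_held_out, None, seed=int(sub[5]))
    hc = held.cells(spec)
    held_scores = pred.values[hc[:, 0], hc[:, 1]]
    rand = rng.integers(0, [n_rows, n_cols], size=(10 * n_held_out, 2))
    rand_scores = pred.values[rand[:, 0], rand[:, 1]]
    return {
        "rho": rho,
        "held_out_auc": float(auc(held_scores, rand_scores)),
        "cv_auc_mean": float(np.mean(cv_aucs)),
        "variables_kept": kept,
        "variables_reduced": reduced,
        "model": model,
        "prediction": pred,
        "truth": truth_grid,
        "occurrences": occ,
        "n": n_presence,
    }


def simulate_scenario(
    out_dir: str | Path, seed: int = 0, scen: ScenarioSpec | None = None
) -> PipelineConfig:
    """Generate and write all pipeline inputs; returns the matching config."""
    scen = scen or ScenarioSpec()
    out_dir = Path(out_dir)
    (out_dir / "env").mkdir(parents=True, exist_ok=True)
    spec = scen.grid_spec()
    rng = np.random.default_rng(seed)

    stack = syn.gen_env_stack(
        spec, scen.n_layers, list(scen.corr_pairs), seed=seed
    )
    layer_names = [f"env{k:02d}" for k in range(scen.n_layers)]
    layer_paths = {}
    for name, grid in zip(layer_names, stack):
        path = out_dir / "env" / f"{name}.asc"
        gio.write_raster(path, grid)
        layer_paths[name] = str(path)

    # per-MU truth: niches driven by two non-collinear layers each
    bias = syn.gen_bias_field(spec, "gradient", seed=seed + 1)
    truths: dict[str, syn.TruthModel] = {}
    occ_sets = []
    truth_params = {}
    driver_pool = [k for k in range(scen.n_layers) if k != 1]  # skip collinear copy
    for m, (mu_id, members) in enumerate(sorted(scen.mus.items())):
        drivers = [driver_pool[(2 * m) % len(driver_pool)],
                   driver_pool[(2 * m + 1) % len(driver_pool)]]
        linear = np.zeros(scen.n_layers)
        quad = np.zeros(scen.n_layers)
        linear[drivers[0]] = 2.0
        linear[drivers[1]] = 1.0
        quad[drivers[0]] = -0.5
        truth = syn.TruthModel(linear, quad, intercept=-1.0, seed=seed)
        truths[mu_id] = truth
        truth_grid = syn.gen_true_suitability(stack, truth)
        gio.write_raster(out_dir / f"truth_{mu_id}.asc", truth_grid)
        truth_params[mu_id] = {
            "linear": linear.tolist(),
            "quadratic": quad.tolist(),
            "intercept": -1.0,
        }
        for si, sp in enumerate(members):
            occ_sets.append(
                syn.gen_occurrences(
                    truth_grid, scen.n_per_species, bias,
                    seed=seed + 100 + 10 * m + si, species=sp,
                )
            )
        polys = syn.gen_edr(truth_grid, scen.edr_cutoff)
        gio.write_geojson(out_dir / f"edr_{mu_id}.geojson", polys)

    # target-group pool: records driven by sampling effort alone
    flat_bias = syn.Grid(spec, np.ones(spec.shape))
    occ_sets.append(
        syn.gen_occurrences(
            flat_bias, scen.n_target_group, bias, seed=seed + 999,
            species="target_group",
        )
    )
    gio.write_occurrences(out_dir / "occurrences.csv", occ_sets)

    pop = syn.gen_population(spec, scen.pop_clusters, seed=seed + 2)
    gio.write_raster(out_dir / "population.asc", pop)

    futures_cfg: dict[str, list[dict[str, str]]] = {}
    for step_idx, step in enumerate(sorted(scen.deltas)):
        deltas = {int(k): v for k, v in scen.deltas[step].items()}
        stacks = syn.gen_future_stacks(
            stack, deltas, scen.n_gcms, seed=seed + 3 + step_idx,
            noise_sd=scen.gcm_noise_sd,
        )
        futures_cfg[step] = []
        for g, fstack in enumerate(stacks):
            mapping = {}
            for k in deltas:
                name = layer_names[k]
                path = out_dir / "env" / f"{name}_{step}_gcm{g}.asc"
                gio.write_raster(path, fstack[k])
                mapping[name] = str(path)
            futures_cfg[step].append(mapping)

    edr_cfg = {
        members[0]: str(out_dir / f"edr_{mu_id}.geojson")
        for mu_id, members in scen.mus.items()
    }
    regions = {m: "region_a" for members in scen.mus.values() for m in members}
    config = PipelineConfig(
        occurrences=str(out_dir / "occurrences.csv"),
        population=str(out_dir / "population.asc"),
        layers=layer_paths,
        mus={k: list(v) for k, v in scen.mus.items()},
        out_dir=str(out_dir / "outputs"),
        futures=futures_cfg,
        edr=edr_cfg,
        regions=regions,
        params=Params(),
        seed=seed,
    )
    config.to_yaml(out_dir / "config.yaml")
    manifest = {
        "seed": seed,
        "grid": {"n_rows": scen.n_rows, "n_cols": scen.n_cols,
                 "origin_lon": scen.origin_lon, "origin_lat": scen.origin_lat,
                 "cell_size": scen.cell_size},
        "truth": truth_params,
        "n_per_species": scen.n_per_species,
        "n_target_group": scen.n_target_group,
    }
    (out_dir / "scenario.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return config
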