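"""End-to-end pipeline: from occurrence points and raster stacks to
suitability models, cost-distance-restricted ranges, SHOI, projections,
shift vectors and validation — driven by a single YAML config.

Stage layout per modelling unit (MU):

1. occurrence pre-filters (per-cell dedup, 75% accuracy cut),
2. target-group background inside the extent-scaled buffer,
3. collinearity screening of candidate variables,
4. 'starting' cross-validated model with all retained variables and
   CV-averaged permutation importances,
5. variable reduction (top-5 kept; importance >= 1% and rank <= n/20),
6. 'reduced' cross-validated model (evaluation) and a 'full' model on
   100% of records (projection),
7. projection to current and per-GCM future climates, ensemble
   median/q10/q90 summaries,
8. balance thresholding, 0-1 rescale, cost-distance restriction
   (>500 CDU removed) and MU splitting with contact-zone fade-out,
9. SHOI, group summaries, richness,
10. validation (CV AUC, partial ROC, EDR comparison) and change/shift
    statistics.

All outputs are plain text (ASCII rasters, CSV, JSON, YAML); a manifest
records every file plus the seeds, so a rerun with the same config and
seed reproduces every output byte for byte.
"""

from __future__ import annotations

import sys
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import background as bg_mod
from . import enm, exposure, futures as fut, io as gio, postprocess as post
from . import predictors, validation
from .grid import Grid, GridSpec
from .io import OccurrenceSet


@dataclass
class Params:
    """Scalar knobs of the pipeline, with their standard defaults."""

    r_max: float = 0.8
    accuracy_frac: float = 0.75
    min_records_exempt: int = 20
    buffer_min_km: float = 1000.0
    buffer_max_km: float = 3000.0
    sparse_records: int = 80          # below this AND restricted -> no products
    top_k: int = 5
    pi_min: float = 1.0               # % permutation importance floor
    rank_divisor: int = 20
    cv_k: int = 10
    train_frac: float = 0.7
    beta: float = 1.0
    max_cdu: float = 500.0
    overlap_cdu: float = 500.0
    cost_floor: float = 1e-6
    proc_iterations: int = 39
    proc_subsample: float = 0.5
    n_perm: int = 2                   # permutations per variable per CV replicate


@dataclass
class PipelineConfig:
    occurrences: str
    population: str
    layers: dict[str, str]                       # name -> raster path
    mus: dict[str, list[str]]                    # MU id -> member species
    out_dir: str
    futures: dict[str, list[dict[str, str]]] = field(default_factory=dict)
    # step label -> list (per GCM) of {layer name -> path} for climate layers
    edr: dict[str, str] = field(default_factory=dict)   # species -> GeoJSON path
    regions: dict[str, str] = field(default_factory=dict)  # species -> region
    keep_overrides: list[list[str]] = field(default_factory=list)
    params: Params = field(default_factory=Params)
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["params"] = Params(**d.get("params", {}))
        return cls(**d)


class MissingInputError(FileNotFoundError):
    pass


def _check_inputs(config: PipelineConfig) -> None:
    """Fail before any computation if a configured input is absent."""
    checks = [("occurrences", config.occurrences), ("population", config.population)]
    checks += [(f"layers[{k}]", v) for k, v in config.layers.items()]
    for step, gcms in config.futures.items():
        for g, mapping in enumerate(gcms):
            checks += [(f"futures[{step}][{g}][{k}]", v) for k, v in mapping.items()]
    checks += [(f"edr[{k}]", v) for k, v in config.edr.items()]
    for name, path in checks:
        if not Path(path).exists():
            raise MissingInputError(f"missing input {name}: {path}")


def _combine_occs(sets: list[OccurrenceSet], name: str, spec: GridSpec) -> OccurrenceSet:
    merged = OccurrenceSet(
        name,
        np.concatenate([s.lon for s in sets]) if sets else np.array([]),
        np.concatenate([s.lat for s in sets]) if sets else np.array([]),
        np.concatenate([s.uncertainty_m for s in sets]) if sets else np.array([]),
    )
    return gio.dedup_per_cell(merged, spec)


def _mask_to_extent(grid: Grid, extent) -> Grid:
    lon_min, lat_min, lon_max, lat_max = extent
    lon, lat = grid.spec.center_lonlats()
    outside = (lon < lon_min) | (lon > lon_max) | (lat < lat_min) | (lat > lat_max)
    v = grid.values.copy()
    v[outside] = np.nan
    return Grid(grid.spec, v)


def _threshold_raw(grid: Grid, t: float) -> Grid:
    """Zero cells below t, keep surviving values on their original scale."""
    v = grid.values.copy()
    v[(v < t) & ~np.isnan(v)] = 0.0
    return Grid(grid.spec, v)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for every MU; returns the output manifest."""
    _check_inputs(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p = config.params

    stack = {name: gio.read_raster(path) for name, path in config.layers.items()}
    spec = next(iter(stack.values())).spec
    pop = gio.read_raster(config.population)
    occ_by_sp = gio.read_occurrences(config.occurrences, spec)
    occ_by_sp = {
        sp: gio.filter_by_accuracy(o, p.accuracy_frac, p.min_records_exempt)
        for sp, o in occ_by_sp.items()
    }
    pool = _combine_occs(list(occ_by_sp.values()), "pool", spec)

    manifest: dict = {"seed": config.seed, "mus": {}, "outputs": []}
    species_clipped: dict[str, Grid] = {}
    species_shoi: dict[str, Grid] = {}
    vector_rows: list[dict] = []

    for mu_index, mu_id in enumerate(sorted(config.mus)):
        t0 = time.perf_counter()
        try:
            mu_out = _run_mu(
                config, mu_id, mu_index, stack, spec, pop, occ_by_sp, pool, out_dir
            )
        except Exception as exc:  # per-MU failure must not sink the run
            print(f"[snakemaps] MU {mu_id} failed: {exc!r}", file=sys.stderr)
            manifest["mus"][mu_id] = {"error": repr(exc)}
            continue
        print(
            f"[snakemaps] MU {mu_id} done in {time.perf_counter() - t0:.1f}s",
            file=sys.stderr,
        )
        manifest["mus"][mu_id] = mu_out["summary"]
        manifest["outputs"].extend(mu_out["files"])
        species_clipped.update(mu_out["species_clipped"])
        species_shoi.update(mu_out["species_shoi"])
        vector_rows.extend(mu_out["vector_rows"])

    # cross-species summaries
    if species_clipped:
        grids = [species_clipped[s] for s in sorted(species_clipped)]
        shois = [species_shoi[s] for s in sorted(species_shoi)]
        for name, grid in [
            ("richness", exposure.richness(grids)),
            ("cumulative_suitability", exposure.group_summary(grids, "sum")),
            ("cumulative_shoi", exposure.group_summary(shois, "sum")),
        ]:
            path = out_dir / f"{name}.asc"
            gio.write_raster(path, grid)
            manifest["outputs"].append(str(path))
    if vector_rows:
        vecs = pd.DataFrame(vector_rows)
        vecs.to_csv(out_dir / "shift_vectors.csv", index=False)
        manifest["outputs"].append(str(out_dir / "shift_vectors.csv"))
        with_region = vecs[vecs["region"] != ""]
        if len(with_region):
            for step, sub in with_region.groupby("step"):
                reg = fut.regional_summary(sub, "region")
                reg.insert(0, "step", step)
                path = out_dir / f"regional_vectors_{step}.csv"
                reg.to_csv(path, index=False)
                manifest["outputs"].append(str(path))

    (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest


def _run_mu(config, mu_id, mu_index, stack, spec, pop, occ_by_sp, pool, out_dir):
    p = config.params
    members = config.mus[mu_id]
    missing = [s for s in members if s not in occ_by_sp]
    if missing:
        raise ValueError(f"MU {mu_id}: no occurrences for {', '.join(missing)}")
    member_occs = {s: occ_by_sp[s] for s in members}
    mu_occs = _combine_occs(list(member_occs.values()), mu_id, spec)
    mu_dir = out_dir / mu_id
    mu_dir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    mu_seed = (config.seed * 1009 + mu_index * 101) % (2**31)

    # --- background -------------------------------------------------------
    width = bg_mod.compute_buffer(mu_occs, p.buffer_min_km, p.buffer_max_km)
    bg = bg_mod.build_background(pool, mu_occs, width, spec, mu_id)
    bg_X = enm.extract_values(stack, bg.cells).dropna()
    pres_X = enm.extract_values(stack, mu_occs.cells(spec)).dropna()

    # --- variable screening ----------------------------------------------
    kept = predictors.collinearity_filter(
        bg_X, p.r_max, [tuple(pair) for pair in config.keep_overrides]
    )
    allow_product = not (len(mu_occs) < p.sparse_records and width <= p.buffer_min_km)

    start_aucs, importances = enm.cv_with_importance(
        pres_X[kept], bg_X[kept], k=p.cv_k, train_frac=p.train_frac,
        seed=mu_seed, n_perm=p.n_perm, beta=p.beta, allow_product=allow_product,
    )
    reduced = predictors.reduce_variables(
        importances, len(mu_occs), p.top_k, p.pi_min, p.rank_divisor
    )
    red_aucs = enm.cross_validate(
        pres_X[reduced], bg_X[reduced], k=p.cv_k, train_frac=p.train_frac,
        seed=mu_seed + 1, beta=p.beta, allow_product=allow_product,
    )
    model = enm.fit_model(
        pres_X[reduced], bg_X[reduced], beta=p.beta, allow_product=allow_product
    )
    model.cv_auc = [float(a) for a in red_aucs]
    model.importances = importances
    (mu_dir / "model.json").write_text(enm.model_to_json(model))
    files.append(str(mu_dir / "model.json"))
    pd.DataFrame(
        {
            "replicate": np.arange(1, p.cv_k + 1),
            "starting_auc": start_aucs,
            "reduced_auc": red_aucs,
        }
    ).to_csv(mu_dir / "cv_report.csv", index=False)
    files.append(str(mu_dir / "cv_report.csv"))
    report = predictors.VariableReport(
        names=list(bg_X.columns),
        correlations=bg_X.corr(),
        importances=importances,
        retained=reduced,
    )
    report.to_frame().to_csv(mu_dir / "variables.csv", index=False)
    files.append(str(mu_dir / "variables.csv"))

    # --- current projection + threshold + CDU restriction -----------------
    raw = _mask_to_extent(enm.predict(model, stack), bg.extent)
    t_star = model.threshold
    thr_raw = _threshold_raw(raw, t_star)          # original scale, for metrics
    rescaled = enm.threshold_and_rescale(raw, t_star)
    finite = thr_raw.values[~np.isnan(thr_raw.values)]
    vmax = finite.max() if finite.size else 0.0
    t_rescaled = t_star / vmax if vmax > 0 else 1.0

    mu_cost = post.cost_distance(raw, mu_occs, p.cost_floor)
    clipped, _ = post.clip_by_cdu(rescaled, mu_cost, p.max_cdu)
    sp_costs = [
        post.cost_distance(raw, member_occs[s], p.cost_floor) for s in members
    ]
    sp_grids = post.split_mu(clipped, sp_costs, p.overlap_cdu, t_rescaled)

    for name, grid in [
        ("suitability_raw", raw),
        ("suitability", rescaled),
        ("suitability_clipped", clipped),
        ("cost_distance", mu_cost.grid),
    ]:
        gio.write_raster(mu_dir / f"{name}.asc", grid)
        files.append(str(mu_dir / f"{name}.asc"))

    species_clipped, species_shoi = {}, {}
    for s, grid in zip(members, sp_grids):
        species_clipped[s] = grid
        species_shoi[s] = exposure.shoi(grid, pop)
        gio.write_raster(mu_dir / f"species_{s}.asc", grid)
        gio.write_raster(mu_dir / f"shoi_{s}.asc", species_shoi[s])
        files += [str(mu_dir / f"species_{s}.asc"), str(mu_dir / f"shoi_{s}.asc")]

    # --- validation -------------------------------------------------------
    val_rows = [
        {"metric": "cv_auc_mean", "species": mu_id, "value": float(np.mean(red_aucs))}
    ]
    try:
        proc = validation.partial_roc(
            clipped, mu_occs, p.proc_iterations, p.proc_subsample, seed=mu_seed + 2
        )
        val_rows += [
            {"metric": "partial_roc_ratio", "species": mu_id, "value": proc.mean_ratio},
            {"metric": "partial_roc_p", "species": mu_id, "value": proc.p_value},
        ]
    except ValueError as exc:
        warnings.warn(f"MU {mu_id}: partial ROC skipped ({exc})")
    for s in members:
        if s in config.edr:
            cmp_ = validation.edr_compare(
                species_clipped[s], gio.read_geojson(config.edr[s])
            )
            val_rows += [
                {"metric": "edr_omission_pct", "species": s, "value": cmp_.omission_pct},
                {"metric": "edr_commission_pct", "species": s, "value": cmp_.commission_pct},
                {"metric": "edr_congruence_pct", "species": s, "value": cmp_.congruence_pct},
            ]
    pd.DataFrame(val_rows).to_csv(mu_dir / "validation.csv", index=False)
    files.append(str(mu_dir / "validation.csv"))

    # --- futures ----------------------------------------------------------
    change_rows, vector_rows = [], []
    cur_clip_mask = np.nan_to_num(mu_cost.grid.values, nan=np.inf) > p.max_cdu
    cur_thr = thr_raw.copy_with(
        np.where(cur_clip_mask, 0.0, thr_raw.values)
    )
    shoi_cur = exposure.shoi(cur_thr, pop)
    for step in sorted(config.futures):
        per_gcm = []
        for mapping in config.futures[step]:
            fstack = dict(stack)
            for name, path in mapping.items():
                fstack[name] = gio.read_raster(path)
            per_gcm.append(_mask_to_extent(enm.predict(model, fstack), bg.extent))
        summary = fut.summarize_gcms(per_gcm)
        for qname, grid in [
            ("median", summary.median), ("q10", summary.q10), ("q90", summary.q90)
        ]:
            gio.write_raster(mu_dir / f"suitability_{step}_{qname}.asc", grid)
            files.append(str(mu_dir / f"suitability_{step}_{qname}.asc"))
            fut_thr = _threshold_raw(grid, t_star)
            fut_thr = fut_thr.copy_with(np.where(cur_clip_mask, 0.0, fut_thr.values))
            metrics = fut.change_metrics(
                cur_thr, fut_thr, shoi_cur, exposure.shoi(fut_thr, pop)
            )
            change_rows.append(
                {
                    "mu": mu_id, "step": step, "quantile": qname,
                    "range_size": metrics.range_size,
                    "expansion": metrics.expansion,
                    "contraction": metrics.contraction,
                    "total_suitability": metrics.total_suitability,
                    "total_shoi": metrics.total_shoi,
                }
            )
            if qname == "median":
                try:
                    vec = fut.shift_vector(fut.centroid(cur_thr), fut.centroid(fut_thr))
                    vector_rows.append(
                        {
                            "mu": mu_id, "step": step,
                            "region": config.regions.get(members[0], ""),
                            "d1_m": vec.d1_m, "d2_deg": vec.d2_deg,
                        }
                    )
                except ValueError as exc:
                    warnings.warn(f"MU {mu_id} {step}: shift vector skipped ({exc})")
    if change_rows:
        pd.DataFrame(change_rows).to_csv(mu_dir / "change_metrics.csv", index=False)
        files.append(str(mu_dir / "change_metrics.csv"))

    summary = {
        "n_presences": int(len(mu_occs)),
        "buffer_km": float(width),
        "background_cells": int(len(bg.cells)),
        "pool_size": int(bg.pool_size),
        "variables_start": list(bg_X.columns),
        "variables_reduced": reduced,
        "threshold": float(t_star),
        "cv_auc_mean": float(np.mean(red_aucs)),
        "allow_product": bool(allow_product),
    }
    return {
        "summary": summary,
        "files": files,
        "species_clipped": species_clipped,
        "species_shoi": species_shoi,
        "vector_rows": vector_rows,
    }
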