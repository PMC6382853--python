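"""End-to-end orchestration of the invasion-modelling study.

A :class:`PipelineConfig` describes one run: where the occurrences and
rasters come from (or the synthetic scenario to generate), the data
preparation settings, the model settings, and which analyses to run. The
pipeline executes the stages

    simulate -> prepare -> fit -> project -> niche -> spread

writing plain-text artifacts (CSV, ASCII rasters, JSON reports) into the
output directory plus a manifest with content hashes, so a rerun with the
same config and seeds is verifiably identical on the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.prepared import prep

from . import landscape as L
from .evaluation import train_test_split_pb
from .maxent import fit_replicates, project
from .niche import compare_niches
from .occurrences import (OccurrenceSet, area_of_occupancy, build_background,
                          downsample_grid, filter_records, time_slice)
from .raster import RasterStack, write_ascii_grid
from .spread import (accumulation_curve, build_neighbor_graph, fit_growth,
                     join_count_test, sequential_models)

__all__ = ["PipelineConfig", "run_pipeline", "split_by_range",
           "correlation_prune", "make_synthetic_study",
           "make_dispersal_contrast"]


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    out_dir: str = "pipeline_out"
    # inputs; None means "generate the synthetic study"
    occurrences_csv: str | None = None
    raster_dir: str | None = None
    native_polygon_geojson: str | None = None
    dataset_mode: str = "native+invaded"      # or "invaded-only"
    seed: int = 0
    # synthetic scenario
    n_rows: int = 64
    n_cols: int = 64
    spread_mode: str = "stratified"
    jump_rate: float = 0.01
    n_years: int = 50
    # preparation
    precision_max: float = 0.1
    cell_km: float = 50.0
    buffer_km: float = 100.0
    n_background: int = 2000
    # model
    beta_multiplier: float = 3.0
    feature_classes: tuple = ("linear", "quadratic", "product", "hinge",
                              "threshold")
    n_knots: int = 9
    n_folds: int = 5
    n_reps: int = 5
    # analyses
    do_niche: bool = True
    do_spread: bool = True
    do_sequential: bool = True
    do_future: bool = True
    future_deltas: dict = field(default_factory=lambda: {"temperature": 2.0})
    cutoffs: tuple = (1970, 1980, 1990, 2000, 2010)
    join_schemes: tuple = ("knn:1", "knn:10", "radius:50")
    niche_grid_size: int = 100
    n_permutations: int = 999
    suitable_threshold: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def snapshot(self) -> dict:
        d = asdict(self)
        d["feature_classes"] = list(self.feature_classes)
        d["cutoffs"] = list(self.cutoffs)
        d["join_schemes"] = list(self.join_schemes)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.snapshot(), sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# standalone operations

def split_by_range(occ: OccurrenceSet, native_polygon: BaseGeometry
                   ) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Split records into (native, invaded) by the native-range polygon.

    Points exactly on the polygon boundary count as native.
    """
    if not native_polygon.is_valid:
        raise ValueError("invalid native-range polygon")
    prepared = prep(native_polygon)
    from shapely.geometry import Point
    inside = np.array([prepared.intersects(Point(lo, la))  # covers boundary
                       for lo, la in zip(occ.lon, occ.lat)])
    native = occ.with_records(occ.records[inside], "split_by_range: native")
    invaded = occ.with_records(occ.records[~inside], "split_by_range: invaded")
    return native, invaded


def correlation_prune(env: np.ndarray, names: list[str], r_max: float = 0.8,
                      priority: list[str] | None = None) -> list[str]:
    """Greedy variable pruning by pairwise Pearson correlation.

    Variables are visited in ``priority`` order (default: given order); one is
    retained unless its |r| with an already-retained variable reaches
    ``r_max``.
    """
    env = np.asarray(env, dtype=float)
    order = priority or list(names)
    retained: list[str] = []
    for name in order:
        j = names.index(name)
        ok = True
        for kept in retained:
            k = names.index(kept)
            r = np.corrcoef(env[:, j], env[:, k])[0, 1]
            if abs(r) >= r_max:
                ok = False
                break
        if ok:
            retained.append(name)
    return retained


# ---------------------------------------------------------------------------
# synthetic study scenario

def make_synthetic_study(seed: int = 0, n_rows: int = 64, n_cols: int = 64,
                         mode: str = "stratified", jump_rate: float = 0.01,
                         n_years: int = 50):
    """The canonical synthetic invasion: five-variable landscape, logistic
    suitability in two of them, founders in a climatically restricted corner
    ("native range"), and a yearly spread trajectory.

    Returns (stack, true suitability grid, occurrences, native polygon).
    """
    spec = L.default_landscape(seed=seed, n_rows=n_rows, n_cols=n_cols)
    stack = L.make_climate_rasters(spec)
    suit = L.default_suitability(stack).grid(stack)
    # founders: the most suitable block within the south-west quadrant, a
    # climatically restricted corner standing in for the native region
    rs = slice(int(n_rows * 0.55), int(n_rows * 0.95))
    cs = slice(int(n_cols * 0.05), int(n_cols * 0.45))
    sub = np.where(np.isnan(suit), -np.inf, suit)[rs, cs]
    rr, cc = np.unravel_index(np.argmax(sub), sub.shape)
    r0, c0 = rr + rs.start, cc + cs.start
    founders = [(r0 + dr, c0 + dc)
                for dr in range(-1, 2) for dc in range(-1, 2)
                if (0 <= r0 + dr < n_rows and 0 <= c0 + dc < n_cols
                    and suit[r0 + dr, c0 + dc] > 0)]
    cfg = L.SpreadConfig(mode=mode, n_years=n_years, start_year=1960,
                         jump_rate=jump_rate if mode == "stratified" else 0.0,
                         seed=seed)
    occ = L.simulate_spread(suit, stack, cfg, founders)
    # native range: a box around the founder block
    from shapely.geometry import box
    lon_f, lat_f = stack.rowcol_to_lonlat(np.array([r0]), np.array([c0]))
    w = 8 * stack.cell_width_deg
    h = 8 * stack.cell_height_deg
    native_poly = box(lon_f[0] - w, lat_f[0] - h, lon_f[0] + w, lat_f[0] + h)
    return stack, suit, occ, native_poly


def make_dispersal_contrast(seed: int = 0, n_rows: int = 96, n_cols: int = 96,
                            exclusion_km: float = 250.0):
    """Paired wave vs jump-dominated invasions for autocorrelation diagnostics.

    Two 18-year simulations on the same continental-scale landscape seed: a
    pure wave (Gaussian local kernel) and a jump-dominated stratified
    invasion (negligible local growth, frequent 800-km jumps). Records within
    ``exclusion_km`` of the founder centre — the "native" core both regimes
    share — are dropped, leaving the invaded records whose spatial pattern
    distinguishes the regimes: a contiguous front (wave) vs scattered,
    mostly isolated nuclei (stratified).

    Returns (stack, wave invaded records, stratified invaded records).
    """
    from .geo import haversine_km
    base = L.default_landscape(seed=seed)
    spec = L.LandscapeSpec(n_rows=n_rows, n_cols=n_cols,
                           lat_range=(20.0, 60.0), lon_range=(-125.0, -75.0),
                           variables=base.variables, seed=seed)
    stack = L.make_climate_rasters(spec)
    suit = L.default_suitability(stack).grid(stack)
    rs = slice(int(n_rows * 0.55), int(n_rows * 0.95))
    cs = slice(int(n_cols * 0.05), int(n_cols * 0.45))
    sub = np.where(np.isnan(suit), -np.inf, suit)[rs, cs]
    rr, cc = np.unravel_index(np.argmax(sub), sub.shape)
    r0, c0 = rr + rs.start, cc + cs.start
    founders = [(r0 + dr, c0 + dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
    lon_f, lat_f = stack.rowcol_to_lonlat(np.array([r0]), np.array([c0]))

    def invaded(cfg):
        occ = L.simulate_spread(suit, stack, cfg, founders)
        d = haversine_km(occ.lon, occ.lat, lon_f[0], lat_f[0])
        return occ.with_records(occ.records[d > exclusion_km], "invaded")

    wave = invaded(L.SpreadConfig(mode="wave", n_years=18, seed=seed))
    strat = invaded(L.SpreadConfig(mode="stratified", n_years=18,
                                   local_kernel_sd=5.0, attempts_per_cell=1,
                                   jump_rate=0.3, jump_kernel_sd=800.0,
                                   seed=seed))
    return stack, wave, strat


# ---------------------------------------------------------------------------
# pipeline stages

def _dump(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


def _mean_se(values) -> dict:
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return {"mean": None, "se": None, "n": 0}
    se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return {"mean": float(v.mean()), "se": se, "n": int(v.size)}


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Execute the pipeline; returns the manifest dictionary.

    ``stages`` restricts execution (earlier stages must have run before, since
    each stage reads its inputs from the output directory).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_stages = ["simulate", "prepare", "fit", "project", "niche", "spread"]
    todo = stages or all_stages
    manifest = {"config": config.snapshot(),
                "config_hash": config.config_hash(),
                "stages": {}}

    for stage in all_stages:
        if stage not in todo:
            continue
        if stage == "niche" and not config.do_niche:
            continue
        if stage == "spread" and not config.do_spread:
            continue
        if stage == "simulate" and config.occurrences_csv is not None:
            continue  # real inputs supplied; nothing to simulate
        t0 = time.perf_counter()
        try:
            written = _STAGES[stage](config, out)
        except Exception as err:
            manifest["stages"][stage] = {"status": "failed", "error": str(err)}
            _dump(manifest, out / "manifest.json")
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
        manifest["stages"][stage] = {
            "status": "ok",
            "wall_seconds": round(time.perf_counter() - t0, 3),
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in written},
        }
    _dump(manifest, out / "manifest.json")
    return manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_simulate(cfg: PipelineConfig, out: Path) -> list[Path]:
    stack, suit, occ, poly = make_synthetic_study(
        seed=cfg.seed, n_rows=cfg.n_rows, n_cols=cfg.n_cols,
        mode=cfg.spread_mode, jump_rate=cfg.jump_rate, n_years=cfg.n_years)
    rdir = out / "rasters"
    stack.write_dir(rdir)
    write_ascii_grid(out / "true_suitability.asc", suit, stack.lon_min,
                     stack.lat_min, stack.cell_width_deg, stack.cell_height_deg)
    occ.to_csv(out / "occurrences.csv")
    (out / "native_range.geojson").write_text(json.dumps(
        {"type": "Feature", "geometry": mapping(poly), "properties": {}}))
    return ([rdir / f"{v}.asc" for v in stack.variables]
            + [rdir / "stack.json", out / "true_suitability.asc",
               out / "occurrences.csv", out / "native_range.geojson"])


def _load_inputs(cfg: PipelineConfig, out: Path):
    occ_path = cfg.occurrences_csv or out / "occurrences.csv"
    raster_path = cfg.raster_dir or out / "rasters"
    poly_path = cfg.native_polygon_geojson or out / "native_range.geojson"
    occ = OccurrenceSet.from_csv(occ_path)
    stack = RasterStack.read_dir(raster_path)
    poly = None
    if Path(poly_path).exists():
        gj = json.loads(Path(poly_path).read_text())
        geom = gj["geometry"] if gj.get("type") == "Feature" else gj
        poly = shape(geom)
    return occ, stack, poly


def _stage_prepare(cfg: PipelineConfig, out: Path) -> list[Path]:
    occ, stack, poly = _load_inputs(cfg, out)
    counts = {"raw": len(occ)}
    filtered = filter_records(occ, precision_max=cfg.precision_max)
    counts["filtered"] = len(filtered)
    thinned = downsample_grid(filtered, cell_km=cfg.cell_km)
    counts["downsampled"] = len(thinned)
    native = invaded = None
    if poly is not None:
        native, invaded = split_by_range(thinned, poly)
        counts["native"] = len(native)
        counts["invaded"] = len(invaded)
        native.to_csv(out / "prepared_native.csv")
        invaded.to_csv(out / "prepared_invaded.csv")
    modelling = thinned
    if cfg.dataset_mode == "invaded-only":
        if invaded is None:
            raise ValueError("invaded-only mode requires a native polygon")
        modelling = invaded
    elif cfg.dataset_mode != "native+invaded":
        raise ValueError(f"unknown dataset_mode {cfg.dataset_mode!r}")
    filtered.to_csv(out / "filtered.csv")
    modelling.to_csv(out / "prepared.csv")
    _dump(counts, out / "record_counts.json")
    written = [out / "filtered.csv", out / "prepared.csv",
               out / "record_counts.json"]
    if poly is not None:
        written += [out / "prepared_native.csv", out / "prepared_invaded.csv"]
    return written


def _stage_fit(cfg: PipelineConfig, out: Path) -> list[Path]:
    occ = OccurrenceSet.from_csv(out / "prepared.csv")
    stack = RasterStack.read_dir(cfg.raster_dir or out / "rasters")
    bg = build_background(occ, stack, buffer_km=cfg.buffer_km,
                          n=cfg.n_background, seed=cfg.seed)
    bg.points.to_csv(out / "background.csv", index=False)
    Xp = stack.extract(occ.lon, occ.lat)
    Xb = stack.extract(bg.lon, bg.lat)
    fits = fit_replicates(Xp, Xb, list(stack.variables),
                          n_folds=cfg.n_folds, n_reps=cfg.n_reps,
                          seed=cfg.seed, beta_multiplier=cfg.beta_multiplier,
                          feature_classes=tuple(cfg.feature_classes),
                          n_knots=cfg.n_knots)
    mdir = out / "models"
    mdir.mkdir(exist_ok=True)
    written = [out / "background.csv"]
    per_fold = []
    for i, (model, res) in enumerate(fits):
        (mdir / f"model_{i:02d}.json").write_text(model.to_json())
        written.append(mdir / f"model_{i:02d}.json")
        per_fold.append(res.to_dict())
    report = {"per_fold": per_fold,
              "aggregated": {k: _mean_se([d[k] for d in per_fold])
                             for k in ("auc_train", "auc_test", "tss",
                                       "tss_threshold")},
              "negative_class": "background"}
    _dump(report, out / "evaluation.json")
    written.append(out / "evaluation.json")
    return written


def _stage_project(cfg: PipelineConfig, out: Path) -> list[Path]:
    from .maxent import MaxentSDM
    stack = RasterStack.read_dir(cfg.raster_dir or out / "rasters")
    models = [MaxentSDM.from_json(p.read_text())
              for p in sorted((out / "models").glob("model_*.json"))]
    written = []

    def project_mean(target: RasterStack, tag: str) -> float:
        clog = np.nanmean([project(m, target).cloglog for m in models], axis=0)
        write_ascii_grid(out / f"projection_{tag}.asc", clog, target.lon_min,
                         target.lat_min, target.cell_width_deg,
                         target.cell_height_deg)
        written.append(out / f"projection_{tag}.asc")
        valid = ~np.isnan(clog)
        return float((clog[valid] >= cfg.suitable_threshold).mean())

    summary = {"current": {"proportion_suitable": project_mean(stack, "current")}}
    if cfg.do_future:
        future = L.make_future_rasters(stack, cfg.future_deltas)
        summary["future"] = {
            "deltas": cfg.future_deltas,
            "proportion_suitable": project_mean(future, "future")}
    _dump(summary, out / "projection_summary.json")
    written.append(out / "projection_summary.json")
    return written


def _stage_niche(cfg: PipelineConfig, out: Path) -> list[Path]:
    stack = RasterStack.read_dir(cfg.raster_dir or out / "rasters")
    native = OccurrenceSet.from_csv(out / "prepared_native.csv")
    invaded = OccurrenceSet.from_csv(out / "prepared_invaded.csv")
    bg_n = build_background(native, stack, buffer_km=cfg.buffer_km,
                            n=cfg.n_background, seed=cfg.seed + 11)
    bg_i = build_background(invaded, stack, buffer_km=cfg.buffer_km,
                            n=cfg.n_background, seed=cfg.seed + 12)
    comp = compare_niches(
        stack.extract(native.lon, native.lat),
        stack.extract(bg_n.lon, bg_n.lat),
        stack.extract(invaded.lon, invaded.lat),
        stack.extract(bg_i.lon, bg_i.lat),
        R=cfg.niche_grid_size, n_perm=cfg.n_permutations, seed=cfg.seed)
    _dump(comp.to_dict(), out / "niche.json")
    return [out / "niche.json"]


def _stage_spread(cfg: PipelineConfig, out: Path) -> list[Path]:
    occ = OccurrenceSet.from_csv(out / "filtered.csv")
    stack = RasterStack.read_dir(cfg.raster_dir or out / "rasters")
    report: dict = {}

    acc = accumulation_curve(occ)
    acc.to_csv(out / "accumulation.csv", index=False)

    years = np.unique(occ.year[~np.isnan(occ.year)]).astype(int)
    aoo_years = [int(y) for y in years if y % 5 == 0] or [int(y) for y in years]
    aoo = [area_of_occupancy(time_slice(occ, y)) for y in aoo_years]
    ok = [i for i, a in enumerate(aoo) if a > 0]
    if len(ok) >= 4:
        lin, log, selected = fit_growth([aoo_years[i] for i in ok],
                                        [aoo[i] for i in ok])
        report["aoo_growth"] = {
            "years": [aoo_years[i] for i in ok],
            "aoo": [aoo[i] for i in ok],
            "linear_aicc": lin.aicc, "loglinear_aicc": log.aicc,
            "loglinear_aicc_response_scale": log.aicc_response_scale,
            "selected": selected,
            "note": "AICc values computed on each family's own response "
                    "scale; see loglinear_aicc_response_scale for the "
                    "Jacobian-corrected cross-family comparison"}

    # presence/absence over all cells of the landscape grid: occupied cells
    # are those holding records
    from .spread import occupancy_labels
    lon_c, lat_c, labels = occupancy_labels(stack, occ)
    join = {}
    for scheme in cfg.join_schemes:
        graph = build_neighbor_graph(lon_c, lat_c, scheme)
        res = join_count_test(graph, labels, n_perm=cfg.n_permutations,
                              seed=cfg.seed)
        join[scheme] = res.to_dict()
    report["join_count"] = join

    if cfg.do_sequential:
        seq = sequential_models(
            occ, stack, cutoffs=cfg.cutoffs, buffer_km=cfg.buffer_km,
            n_background=min(cfg.n_background, 1000), seed=cfg.seed,
            beta_multiplier=cfg.beta_multiplier,
            feature_classes=tuple(cfg.feature_classes), n_knots=cfg.n_knots)
        report["sequential"] = [{
            "cutoff": r.cutoff, "n_presence": r.n_presence, "aoo": r.aoo,
            "auc_internal": r.internal.auc_test, "tss_internal": r.internal.tss,
            "auc_forecast": None if r.forecast is None else r.forecast.auc_test,
            "tss_forecast": None if r.forecast is None else r.forecast.tss,
            "forecast_note": r.forecast_note,
            "proportion_suitable": r.proportion_suitable,
        } for r in seq]

    _dump(report, out / "spread.json")
    return [out / "accumulation.csv", out / "spread.json"]


_STAGES = {"simulate": _stage_simulate, "prepare": _stage_prepare,
           "fit": _stage_fit, "project": _stage_project,
           "niche": _stage_niche, "spread": _stage_spread}
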