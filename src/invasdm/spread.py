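"""Range-expansion analyses.

Covers the temporal and spatial signatures of an invasion: record
accumulation, area-of-occupancy (AOO) growth with linear vs log-linear model
selection by AICc, sequential historical suitability models with
forecast-skill evaluation, and join-count spatial autocorrelation at several
neighbourhood scales. Wave-like spread leaves strong fine-scale spatial
autocorrelation among occurrences; stratified spread (rare long-distance
jumps) weakens it at the finest scale while preserving it at coarser scales —
the diagnostic contrast these analyses are built to detect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .evaluation import (EvalResult, MessSurface, evaluate, evaluate_forecast,
                         mess, train_test_split_pb)
from .geo import EARTH_RADIUS_KM
from .maxent import MaxentSDM, Prediction, project
from .occurrences import (OccurrenceSet, area_of_occupancy, build_background,
                          time_slice)
from .raster import RasterStack

__all__ = ["GrowthFit", "NeighborGraph", "JoinCountResult", "SequentialResult",
           "accumulation_curve", "fit_growth", "sequential_models",
           "build_neighbor_graph", "join_count_test", "join_count_exact_p",
           "occupancy_labels"]


# ---------------------------------------------------------------------------
# temporal dynamics

def accumulation_curve(occ: OccurrenceSet) -> pd.DataFrame:
    """Cumulative record count per calendar year (records without a year are
    excluded)."""
    yr = occ.year
    yr = yr[~np.isnan(yr)].astype(int)
    if yr.size == 0:
        return pd.DataFrame({"year": [], "n_new": [], "cumulative": []})
    counts = pd.Series(yr).value_counts().sort_index()
    years = np.arange(counts.index.min(), counts.index.max() + 1)
    n_new = counts.reindex(years, fill_value=0)
    return pd.DataFrame({"year": years, "n_new": n_new.to_numpy(),
                         "cumulative": n_new.cumsum().to_numpy()})


@dataclass
class GrowthFit:
    """One least-squares fit of AOO growth against year."""

    form: str                 # "linear" or "log-linear"
    intercept: float
    slope: float
    rss: float
    n: int
    aicc: float
    # for the log form only: AICc transported to the response scale via the
    # log-transform Jacobian, the only scale on which the two families are
    # strictly comparable
    aicc_response_scale: float = np.nan


def _aicc_ls(rss: float, n: int, k: int = 3) -> float:
    """AICc of a Gaussian least-squares fit; k counts intercept, slope, and
    the error variance."""
    if n <= k + 1:
        raise ValueError("AICc undefined: n must exceed k + 1")
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_growth(years, aoo) -> tuple[GrowthFit, GrowthFit, str]:
    """Fit AOO ~ year and log(AOO) ~ year; select the lower-AICc form.

    Returns (linear fit, log-linear fit, selected form). The AICc values of
    the two families are computed on their own response scales — directly
    comparable only in form, which is flagged via ``aicc_response_scale`` on
    the log fit (Jacobian-corrected to the raw-AOO scale).
    """
    years = np.asarray(years, dtype=float)
    aoo = np.asarray(aoo, dtype=float)
    if years.size < 4:
        raise ValueError("need at least 4 (year, AOO) points")
    if np.any(aoo <= 0):
        raise ValueError("AOO must be positive for the log-linear form")
    n = years.size

    def ls(y):
        A = np.column_stack([np.ones(n), years])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(((y - A @ coef) ** 2).sum())
        return coef, rss

    coef_lin, rss_lin = ls(aoo)
    lin = GrowthFit("linear", float(coef_lin[0]), float(coef_lin[1]),
                    rss_lin, n, _aicc_ls(rss_lin, n))
    logy = np.log(aoo)
    coef_log, rss_log = ls(logy)
    aicc_log = _aicc_ls(rss_log, n)
    log = GrowthFit("log-linear", float(coef_log[0]), float(coef_log[1]),
                    rss_log, n, aicc_log,
                    aicc_response_scale=aicc_log + 2.0 * logy.sum())
    selected = "linear" if lin.aicc <= log.aicc else "log-linear"
    return lin, log, selected


# ---------------------------------------------------------------------------
# sequential historical models

@dataclass
class SequentialResult:
    cutoff: int
    n_presence: int
    aoo: int
    model: MaxentSDM
    internal: EvalResult
    forecast: EvalResult | None
    forecast_note: str
    proportion_suitable: float
    prediction: Prediction = field(repr=False, default=None)
    mess_surface: MessSurface = field(repr=False, default=None)


def sequential_models(occ: OccurrenceSet, rasters: RasterStack,
                      cutoffs=(1970, 1980, 1990, 2000, 2010),
                      min_presences: int = 20, buffer_km: float = 100.0,
                      n_background: int = 2000, seed: int = 0,
                      suitable_threshold: float = 0.5,
                      **model_kw) -> list[SequentialResult]:
    """Rebuild the suitability model at each historical cutoff and score it.

    For each cutoff year: records are sliced to ``year <= cutoff``, a fresh
    latitude-weighted background is drawn from buffers around the sliced
    presences, a model is fitted on an 80% training split and evaluated
    internally on the withheld 20%, and its forecast skill is scored against
    records from *after* the cutoff restricted to analogous climate (MESS > 0,
    computed from the slice's background). ``proportion_suitable`` is the
    fraction of projected cells with cloglog >= ``suitable_threshold``.
    """
    results = []
    for i, cutoff in enumerate(cutoffs):
        sliced = time_slice(occ, cutoff)
        if len(sliced) < min_presences:
            warnings.warn(f"cutoff {cutoff}: only {len(sliced)} records "
                          f"(< {min_presences}); skipped")
            continue
        bg = build_background(sliced, rasters, buffer_km=buffer_km,
                              n=n_background, seed=seed + i)
        Xp = rasters.extract(sliced.lon, sliced.lat)
        Xb = rasters.extract(bg.lon, bg.lat)
        Xp_tr, Xb_tr, Xp_te, Xb_te = train_test_split_pb(Xp, Xb, 0.2,
                                                         seed=seed + i)
        model = MaxentSDM(**model_kw)
        model.fit_presence_background(Xp_tr, Xb_tr, list(rasters.variables))
        internal = evaluate(model, Xp_tr, Xb_tr, Xp_te, Xb_te)

        mess_surf = mess(Xb, rasters, list(rasters.variables))
        yr = occ.year
        future = ~np.isnan(yr) & (yr > cutoff)
        forecast, note = None, ""
        if future.sum() == 0:
            note = "no records after cutoff; forecast undefined"
        else:
            Xf = rasters.extract(occ.lon[future], occ.lat[future])
            try:
                forecast = evaluate_forecast(
                    model, Xf, Xb, (occ.lon[future], occ.lat[future]),
                    (bg.lon, bg.lat), mess_surf)
            except ValueError as err:
                note = str(err)

        pred = project(model, rasters)
        valid = ~np.isnan(pred.cloglog)
        prop = float((pred.cloglog[valid] >= suitable_threshold).mean())
        results.append(SequentialResult(
            cutoff=cutoff, n_presence=len(sliced),
            aoo=area_of_occupancy(sliced), model=model, internal=internal,
            forecast=forecast, forecast_note=note, proportion_suitable=prop,
            prediction=pred, mess_surface=mess_surf))
    return results


# ---------------------------------------------------------------------------
# join-count spatial autocorrelation

@dataclass
class NeighborGraph:
    """Symmetric spatial neighbour graph over point sites."""

    n: int
    edges: np.ndarray            # (E, 2) int array, i < j, unique
    scheme: str

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg

    def to_edgelist_csv(self, path) -> None:
        pd.DataFrame(self.edges, columns=["i", "j"]).to_csv(path, index=False)


def build_neighbor_graph(lon, lat, scheme: str = "knn:1") -> NeighborGraph:
    """Neighbour graph on haversine distances.

    ``scheme`` is "knn:<k>" (k nearest neighbours, symmetrized by edge union)
    or "radius:<km>" (all pairs within the radius; symmetric by
    construction).
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    n = lon.size
    if n < 2:
        raise ValueError("need at least 2 sites")
    pts = np.radians(np.column_stack([lat, lon]))  # sklearn wants (lat, lon)
    kind, _, value = scheme.partition(":")
    if kind == "knn":
        k = int(value)
        if k >= n:
            raise ValueError(f"k={k} must be smaller than n={n}")
        nn = NearestNeighbors(n_neighbors=k + 1, metric="haversine").fit(pts)
        _, idx = nn.kneighbors(pts)
        pairs = {(min(i, j), max(i, j))
                 for i, row in enumerate(idx) for j in row[1:]}
    elif kind == "radius":
        radius = float(value) / EARTH_RADIUS_KM
        nn = NearestNeighbors(metric="haversine").fit(pts)
        idx = nn.radius_neighbors(pts, radius=radius, return_distance=False)
        pairs = {(min(i, j), max(i, j))
                 for i, row in enumerate(idx) for j in row if i != j}
    else:
        raise ValueError(f"unknown scheme {scheme!r}; use knn:<k> or radius:<km>")
    edges = np.array(sorted(pairs), dtype=int).reshape(-1, 2)
    return NeighborGraph(n=n, edges=edges, scheme=scheme)


@dataclass
class JoinCountResult:
    pp: int
    pa: int
    aa: int
    perm_mean_pp: float
    perm_sd_pp: float
    p_value: float
    n_perm: int

    def to_dict(self) -> dict:
        return {"pp": self.pp, "pa": self.pa, "aa": self.aa,
                "perm_mean_pp": self.perm_mean_pp,
                "perm_sd_pp": self.perm_sd_pp, "p_value": self.p_value,
                "n_perm": self.n_perm}


def join_count_test(graph: NeighborGraph, labels, n_perm: int = 999,
                    seed: int | None = None) -> JoinCountResult:
    """One-sided join-count test for positive presence-presence clustering.

    Observed presence-presence (PP) joins are compared with ``n_perm``
    random relabellings of the sites; the pseudo p-value is
    (1 + #{PP_sim >= PP_obs}) / (n_perm + 1), so p is never exactly 0.
    """
    lab = np.asarray(labels, dtype=bool)
    if lab.size != graph.n:
        raise ValueError("labels length must equal number of graph nodes")
    if lab.all() or not lab.any():
        raise ValueError("need at least one presence and one absence")
    a, b = graph.edges[:, 0], graph.edges[:, 1]
    pp = int(np.sum(lab[a] & lab[b]))
    aa = int(np.sum(~lab[a] & ~lab[b]))
    pa = graph.n_edges - pp - aa

    rng = np.random.default_rng(seed)
    sims = np.empty(n_perm, dtype=int)
    for k in range(n_perm):
        perm = rng.permutation(lab)
        sims[k] = np.sum(perm[a] & perm[b])
    p = (1.0 + np.sum(sims >= pp)) / (n_perm + 1.0)
    return JoinCountResult(pp=pp, pa=pa, aa=aa,
                           perm_mean_pp=float(sims.mean()),
                           perm_sd_pp=float(sims.std()),
                           p_value=float(p), n_perm=n_perm)


def join_count_exact_p(graph: NeighborGraph, labels) -> float:
    """Exact one-sided join-count p by exhausting all label placements.

    Enumerates every way of placing the observed number of presences on the
    nodes; p = P(PP_sim >= PP_obs) under that uniform null. Feasible only for
    small graphs (C(n, m) placements).
    """
    from itertools import combinations
    from math import comb
    lab = np.asarray(labels, dtype=bool)
    m = int(lab.sum())
    if comb(graph.n, m) > 2_000_000:
        raise ValueError("too many placements for exact enumeration")
    a, b = graph.edges[:, 0], graph.edges[:, 1]
    pp_obs = int(np.sum(lab[a] & lab[b]))
    count = total = 0
    for pres in combinations(range(graph.n), m):
        sim = np.zeros(graph.n, dtype=bool)
        sim[list(pres)] = True
        count += int(np.sum(sim[a] & sim[b]) >= pp_obs)
        total += 1
    return count / total


def occupancy_labels(stack: RasterStack, occ: OccurrenceSet,
                     buffer_km: float | None = None
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Presence/absence labels over the cells of a raster grid.

    Returns (lon, lat, labels) with a cell labelled presence when at least
    one record falls in it — the node set for grid-based join-count
    analyses. With ``buffer_km`` set, the node set is restricted to cells
    within that distance of a record (the dissolved presence buffer); this
    conditions the permutation null on where records broadly are, which is
    the appropriate reference for fine-scale (nearest-neighbour) questions.
    The unrestricted grid keeps regional intensity variation in play and is
    the reference for coarse-scale clustering.
    """
    from .geo import haversine_km
    rows, cols = stack.valid_rowcol()
    r_occ, c_occ = stack.lonlat_to_rowcol(occ.lon, occ.lat)
    occupied = np.zeros(stack.shape, dtype=bool)
    occupied[r_occ, c_occ] = True
    lon, lat = stack.rowcol_to_lonlat(rows, cols)
    labels = occupied[rows, cols]
    if buffer_km is not None:
        keep = np.zeros(lon.size, dtype=bool)
        for start in range(0, lon.size, 2048):
            sl = slice(start, start + 2048)
            d = haversine_km(lon[sl, None], lat[sl, None],
                             occ.lon[None, :], occ.lat[None, :])
            keep[sl] = (d <= buffer_km).any(axis=1)
        lon, lat, labels = lon[keep], lat[keep], labels[keep]
    return lon, lat, labels
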