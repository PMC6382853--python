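"""Synthetic landscapes with known ground truth.

Real bioclimatic rasters and occurrence databases are large, access-restricted
and uncontrolled; every downstream stage of this package is therefore
exercised on synthetic landscapes where the truth is known by construction:

* smooth climate gradients plus spatially correlated noise
  (:func:`make_climate_rasters`),
* a logistic "true suitability" surface (:class:`TrueSuitability`),
* spatially biased presence sampling (:func:`sample_occurrences`),
* a yearly invasion simulator with wave-like (short-distance kernel only) or
  stratified (short-distance plus rare long-distance jumps) dispersal
  (:func:`simulate_spread`),
* "future climate" scenarios produced by additive offsets
  (:func:`make_future_rasters`).

All operations are pure functions of their inputs and seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .geo import haversine_km
from .occurrences import OccurrenceSet
from .raster import RasterStack

__all__ = [
    "VariableSpec", "LandscapeSpec", "TrueSuitability", "SpreadConfig",
    "make_climate_rasters", "sample_occurrences", "simulate_spread",
    "make_future_rasters", "default_landscape", "default_suitability",
]


@dataclass
class VariableSpec:
    """One synthetic climate variable.

    ``gradient`` is the per-cell change along ``direction`` ("north", "east"
    or "northeast"); noise is white noise smoothed with a Gaussian kernel of
    SD ``noise_length`` cells, rescaled to SD ``noise_amp``.
    """

    name: str
    direction: str = "north"
    gradient: float = 0.1
    noise_amp: float = 0.0
    noise_length: float = 5.0


@dataclass
class LandscapeSpec:
    n_rows: int = 64
    n_cols: int = 64
    lat_range: tuple[float, float] = (25.0, 50.0)
    lon_range: tuple[float, float] = (-110.0, -80.0)
    variables: list[VariableSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 10 or self.n_cols < 10:
            raise ValueError("landscape must be at least 10 x 10 cells")
        lo, hi = self.lat_range
        if not (-90 <= lo < hi <= 90):
            raise ValueError("lat_range must be increasing within [-90, 90]")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")


@dataclass
class TrueSuitability:
    """Known logistic suitability: sigmoid(intercept + sum b1*x + b2*x^2).

    ``linear`` and ``quadratic`` map variable name -> coefficient; variables
    not listed do not influence suitability (they are decoys for the
    variable-attribution analyses).
    """

    linear: dict[str, float]
    quadratic: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0

    def grid(self, stack: RasterStack) -> np.ndarray:
        eta = np.full(stack.shape, self.intercept, dtype=float)
        for name, b in self.linear.items():
            eta += b * stack.band(name)
        for name, b in self.quadratic.items():
            eta += b * stack.band(name) ** 2
        out = 1.0 / (1.0 + np.exp(-eta))
        out[stack.mask] = np.nan
        return out


@dataclass
class SpreadConfig:
    """Parameters of the yearly colonization simulator.

    ``mode`` "wave" spreads only through the local Gaussian kernel (truncated
    at 3 SD); "stratified" additionally fires long-distance jumps from each
    colonized cell with probability ``jump_rate`` per year, displaced by a
    Gaussian of SD ``jump_kernel_sd`` km. Establishment at a target cell is
    accepted with probability equal to its true suitability.
    """

    mode: str = "stratified"
    n_years: int = 40
    start_year: int = 1960
    local_kernel_sd: float = 30.0     # km
    jump_rate: float = 0.01           # per colonized cell per year
    jump_kernel_sd: float = 500.0     # km
    attempts_per_cell: int = 3        # local dispersal attempts per cell-year
    seed: int = 0

    def __post_init__(self):
        if self.mode not in {"wave", "stratified"}:
            raise ValueError("mode must be 'wave' or 'stratified'")
        if not 0.0 <= self.jump_rate <= 1.0:
            raise ValueError("jump_rate must be a probability")
        if self.mode == "wave" and self.jump_rate != 0.0:
            # wave mode is by definition jump-free
            object.__setattr__(self, "jump_rate", 0.0)


# ---------------------------------------------------------------------------

def _correlated_noise(shape, amp, length, rng) -> np.ndarray:
    """White noise smoothed to correlation length ``length`` cells, SD amp."""
    white = rng.standard_normal(shape)
    if length > 0:
        smooth = gaussian_filter(white, sigma=length, mode="reflect")
    else:
        smooth = white
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    return amp * smooth


def make_climate_rasters(spec: LandscapeSpec) -> RasterStack:
    """Build one gradient-plus-noise grid per variable; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    rows = np.arange(spec.n_rows)[:, None]
    cols = np.arange(spec.n_cols)[None, :]
    bands = []
    for var in spec.variables:
        if var.direction == "north":       # row 0 is northernmost
            base = var.gradient * (spec.n_rows - 1 - rows) * np.ones_like(cols, float)
        elif var.direction == "east":
            base = var.gradient * cols * np.ones_like(rows, float)
        elif var.direction == "northeast":
            base = var.gradient * ((spec.n_rows - 1 - rows) + cols) / 2.0
        else:
            raise ValueError(f"unknown gradient direction {var.direction!r}")
        base = np.broadcast_to(base, (spec.n_rows, spec.n_cols)).copy()
        if var.noise_amp > 0:
            base += _correlated_noise((spec.n_rows, spec.n_cols),
                                      var.noise_amp, var.noise_length, rng)
        bands.append(base)
    return RasterStack([v.name for v in spec.variables], np.stack(bands),
                       lon_min=spec.lon_range[0], lon_max=spec.lon_range[1],
                       lat_min=spec.lat_range[0], lat_max=spec.lat_range[1],
                       meta={"seed": spec.seed})


def sample_occurrences(suit_grid: np.ndarray, stack: RasterStack, n: int,
                       bias: np.ndarray | None = None, seed: int | None = None,
                       year: int | None = None, source: str = "synthetic") -> OccurrenceSet:
    """Draw presence points with probability proportional to suitability x bias.

    Coordinates are jittered uniformly within the sampled cell. ``bias``
    emulates uneven survey effort; omit it for effort-free sampling.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    w = np.where(np.isnan(suit_grid), 0.0, suit_grid).astype(float)
    if bias is not None:
        if bias.shape != w.shape:
            raise ValueError("bias grid not congruent with suitability grid")
        w = w * np.where(np.isnan(bias), 0.0, bias)
    total = w.sum()
    if total <= 0:
        raise ValueError("all sampling weights are zero")
    flat = rng.choice(w.size, size=n, replace=True, p=(w / total).ravel())
    r, c = np.unravel_index(flat, w.shape)
    lon, lat = stack.rowcol_to_lonlat(r, c)
    lon = lon + rng.uniform(-0.5, 0.5, n) * stack.cell_width_deg
    lat = lat + rng.uniform(-0.5, 0.5, n) * stack.cell_height_deg
    df = pd.DataFrame({
        "id": [f"s{i}" for i in range(n)],
        "longitude": lon, "latitude": lat,
        "year": np.nan if year is None else year,
        "precision": 1e-4, "source": source, "is_county_centroid": False,
    })
    return OccurrenceSet(df, [f"sample_occurrences: n={n} seed={seed}"])


def simulate_spread(suit_grid: np.ndarray, stack: RasterStack,
                    cfg: SpreadConfig,
                    founder_cells: list[tuple[int, int]]) -> OccurrenceSet:
    """Yearly invasion from founder cells; one record per first colonization.

    Wave and stratified modes share one code path (wave simply has
    ``jump_rate = 0``), so a stratified run with the jump rate set to zero is
    trajectory-identical to the wave run under the same seed.
    """
    if not founder_cells:
        raise ValueError("founder_cells must be non-empty")
    n_rows, n_cols = suit_grid.shape
    suit = np.where(np.isnan(suit_grid), 0.0, suit_grid)
    colonized = np.zeros((n_rows, n_cols), dtype=bool)
    year_col = {}
    for (r, c) in founder_cells:
        if not (0 <= r < n_rows and 0 <= c < n_cols):
            raise ValueError("founder cell outside grid")
        if suit[r, c] <= 0:
            raise ValueError("founder cell has zero suitability or is masked")
        colonized[r, c] = True
        year_col[(r, c)] = cfg.start_year

    rng = np.random.default_rng(cfg.seed)
    # km -> cell sizes; lon spacing shrinks with latitude, use mid-latitude
    lat_mid = 0.5 * (stack.lat_min + stack.lat_max)
    km_per_deg_lat = haversine_km(0, lat_mid - 0.5, 0, lat_mid + 0.5)
    km_per_deg_lon = haversine_km(-0.5, lat_mid, 0.5, lat_mid)
    cell_h_km = stack.cell_height_deg * km_per_deg_lat
    cell_w_km = stack.cell_width_deg * km_per_deg_lon

    def settle(src_r, src_c, dy_km, dx_km, year):
        """Apply dispersal displacements; colonize accepted, in-bounds cells."""
        tr = src_r + np.rint(dy_km / cell_h_km).astype(int)
        tc = src_c + np.rint(dx_km / cell_w_km).astype(int)
        u = rng.uniform(size=tr.size)
        ok = (tr >= 0) & (tr < n_rows) & (tc >= 0) & (tc < n_cols)
        tr_c, tc_c = np.clip(tr, 0, n_rows - 1), np.clip(tc, 0, n_cols - 1)
        ok &= ~colonized[tr_c, tc_c] & (u < suit[tr_c, tc_c])
        for r, c in zip(tr[ok], tc[ok]):
            rc = (int(r), int(c))
            if not colonized[rc]:
                colonized[rc] = True
                year_col[rc] = year

    for step in range(1, cfg.n_years + 1):
        sources = np.argwhere(colonized)
        src_r = np.repeat(sources[:, 0], cfg.attempts_per_cell)
        src_c = np.repeat(sources[:, 1], cfg.attempts_per_cell)
        dy = rng.normal(0.0, cfg.local_kernel_sd, src_r.size)
        dx = rng.normal(0.0, cfg.local_kernel_sd, src_r.size)
        # radial truncation at 3 SD bounds the wave front speed
        norm = np.hypot(dy, dx)
        lim = 3.0 * cfg.local_kernel_sd
        scale = np.where(norm > lim, lim / np.maximum(norm, 1e-12), 1.0)
        # colonization within a year is simultaneous: targets are judged
        # against occupancy at the start of the year, applied as found
        year = cfg.start_year + step
        settle(src_r, src_c, dy * scale, dx * scale, year)
        jump_u = rng.uniform(size=len(sources))
        jumpers = jump_u < cfg.jump_rate
        if jumpers.any():
            jr, jc = sources[jumpers, 0], sources[jumpers, 1]
            jdy = rng.normal(0.0, cfg.jump_kernel_sd, jr.size)
            jdx = rng.normal(0.0, cfg.jump_kernel_sd, jr.size)
            settle(jr, jc, jdy, jdx, year)

    cells = sorted(year_col)
    rows = np.array([rc[0] for rc in cells])
    cols = np.array([rc[1] for rc in cells])
    lon, lat = stack.rowcol_to_lonlat(rows, cols)
    df = pd.DataFrame({
        "id": [f"c{r}_{c}" for r, c in cells],
        "longitude": lon, "latitude": lat,
        "year": [year_col[rc] for rc in cells],
        "precision": 1e-4, "source": f"spread:{cfg.mode}",
        "is_county_centroid": False,
    })
    return OccurrenceSet(df, [f"simulate_spread: {cfg.mode} seed={cfg.seed}"])


def make_future_rasters(stack: RasterStack, deltas: dict[str, float]) -> RasterStack:
    """Additive climate-change scenario: shift listed variables, copy the rest."""
    for name in deltas:
        if name not in stack.variables:
            raise KeyError(f"unknown variable {name!r}")
    out = stack.copy()
    for name, dv in deltas.items():
        i = out.variables.index(name)
        out.values[i] = out.values[i] + dv
    out.meta = {**out.meta, "deltas": dict(deltas)}
    return out


# ---------------------------------------------------------------------------
# canonical study landscape

def default_landscape(seed: int = 0, n_rows: int = 64, n_cols: int = 64) -> LandscapeSpec:
    """The package's reference synthetic landscape: five climate variables,
    two of which (temperature, precipitation) drive true suitability while
    three are correlated-noise decoys."""
    variables = [
        VariableSpec("temperature", "north", gradient=0.25, noise_amp=1.0,
                     noise_length=5.0),
        VariableSpec("precipitation", "east", gradient=0.25, noise_amp=1.0,
                     noise_length=5.0),
        VariableSpec("seasonality", "northeast", gradient=0.04, noise_amp=2.5,
                     noise_length=8.0),
        VariableSpec("radiation", "east", gradient=0.05, noise_amp=2.0,
                     noise_length=4.0),
        VariableSpec("moisture", "north", gradient=0.05, noise_amp=2.0,
                     noise_length=6.0),
    ]
    return LandscapeSpec(n_rows=n_rows, n_cols=n_cols, variables=variables,
                         seed=seed)


def default_suitability(stack: RasterStack) -> TrueSuitability:
    """Logistic suitability driven by temperature and precipitation only.

    The logistic is centred on the lower-third quantile of the linear
    predictor, so the cool/dry corner of the landscape (where invasions are
    seeded) is moderately suitable while most of the grid is suitable — an
    invader far from equilibrium with a broadly suitable environment.
    """
    eta = (0.6 * stack.band("temperature") + 0.6 * stack.band("precipitation"))
    center = np.nanquantile(eta, 0.30)
    return TrueSuitability(
        linear={"temperature": 0.6, "precipitation": 0.6},
        intercept=-center,
    )
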