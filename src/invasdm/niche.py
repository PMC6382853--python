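"""Niche quantification in environmental space (PCA-env).

The native/invaded niche comparison runs in the plane of the first two
principal components of the pooled background environments. Occurrence
density ``o`` and environmental availability ``e`` are kernel-smoothed onto a
shared R x R grid; occupancy ``z = o/e`` (rescaled to max 1) corrects observed
density for how common each environment is. From the z grids come Schoener's
D overlap, niche expansion/stability/unfilling, centroid shifts, and a
permutation test of niche similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

__all__ = ["PcaEnv", "NicheGrid", "NicheComparison", "pca_env", "density_grid",
           "schoeners_d", "niche_indices", "similarity_test", "centroid_shift",
           "compare_niches"]


@dataclass
class PcaEnv:
    """PCA of pooled (centered, scaled) background environments."""

    scaler: StandardScaler
    pca: PCA

    def scores(self, X: np.ndarray) -> np.ndarray:
        return self.pca.transform(self.scaler.transform(np.asarray(X, float)))

    @property
    def loadings(self) -> np.ndarray:
        return self.pca.components_

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.pca.explained_variance_ratio_


def pca_env(native_bg_env: np.ndarray, invaded_bg_env: np.ndarray,
            n_components: int = 2) -> PcaEnv:
    """Fit the shared environmental axes on the pooled backgrounds."""
    pooled = np.vstack([np.asarray(native_bg_env, float),
                        np.asarray(invaded_bg_env, float)])
    if pooled.shape[0] < 3 or pooled.shape[1] < 2:
        raise ValueError("need >= 3 points and >= 2 variables for PCA-env")
    scaler = StandardScaler().fit(pooled)
    Z = scaler.transform(pooled)
    if not np.any(Z.std(axis=0) > 0):
        raise ValueError("environmental data carry no variation")
    pca = PCA(n_components=n_components).fit(Z)
    return PcaEnv(scaler=scaler, pca=pca)


@dataclass
class NicheGrid:
    """Availability-corrected occurrence density on the PC1-PC2 grid."""

    o: np.ndarray                 # occurrence density
    e: np.ndarray                 # availability (background) density
    z: np.ndarray                 # occupancy = o/e, rescaled to max 1
    x_edges: np.ndarray
    y_edges: np.ndarray
    range_id: str = ""
    bandwidth: tuple[float, float] = (np.nan, np.nan)

    @property
    def z_hat(self) -> np.ndarray:
        """z normalized to sum to 1 (the comparison scale for D)."""
        tot = self.z.sum()
        if tot == 0:
            raise ValueError("all-zero occupancy grid")
        return self.z / tot

    def centroid(self, weights: np.ndarray) -> np.ndarray:
        xc = (self.x_edges[:-1] + self.x_edges[1:]) / 2.0
        yc = (self.y_edges[:-1] + self.y_edges[1:]) / 2.0
        w = weights / weights.sum()
        return np.array([(w.sum(axis=1) * xc).sum(), (w.sum(axis=0) * yc).sum()])


def _silverman(scores: np.ndarray) -> float:
    n = len(scores)
    sd = scores.std(ddof=1) if n > 1 else 1.0
    return 1.06 * max(sd, 1e-12) * n ** (-1 / 5)


def density_grid(occ_scores: np.ndarray, bg_scores: np.ndarray,
                 bounds: tuple[np.ndarray, np.ndarray] | None = None,
                 R: int = 100, range_id: str = "",
                 envelope_mass: float = 0.99) -> NicheGrid:
    """Kernel-smoothed o and e densities on a shared R x R grid.

    Bandwidths follow Silverman's rule per PC axis (computed from the
    background scores, which define the availability surface). ``bounds`` are
    (x_edges, y_edges); pass the same bounds for every range being compared.

    Occupancy ``z = o/e`` is only defined inside the availability envelope:
    the smallest set of highest-availability cells holding ``envelope_mass``
    of the e density. Outside it the kernel tails make o/e a ratio of two
    vanishing numbers — numerically explosive and ecologically meaningless —
    so z is set to 0 there.
    """
    occ = np.asarray(occ_scores, float)
    bg = np.asarray(bg_scores, float)
    if occ.shape[0] < 5:
        raise ValueError("need >= 5 occurrences for a density grid")
    if bounds is None:
        lo = bg.min(axis=0)
        hi = bg.max(axis=0)
        pad = 0.05 * (hi - lo)
        bounds = (np.linspace(lo[0] - pad[0], hi[0] + pad[0], R + 1),
                  np.linspace(lo[1] - pad[1], hi[1] + pad[1], R + 1))
    x_edges, y_edges = bounds
    inside = ((occ[:, 0] >= x_edges[0]) & (occ[:, 0] <= x_edges[-1])
              & (occ[:, 1] >= y_edges[0]) & (occ[:, 1] <= y_edges[-1]))
    if not inside.any():
        raise ValueError("all occurrences fall outside the grid bounds")

    bw = (_silverman(bg[:, 0]), _silverman(bg[:, 1]))
    dx = x_edges[1] - x_edges[0]
    dy = y_edges[1] - y_edges[0]
    sigma = (bw[0] / dx, bw[1] / dy)

    def smooth(pts):
        h, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=[x_edges, y_edges])
        return gaussian_filter(h, sigma=sigma, mode="constant")

    o = smooth(occ[inside])
    e = smooth(bg)
    # availability envelope: highest-e cells holding `envelope_mass` of e
    flat = np.sort(e.ravel())[::-1]
    csum = np.cumsum(flat)
    cut_idx = int(np.searchsorted(csum, envelope_mass * csum[-1]))
    e_floor = flat[min(cut_idx, flat.size - 1)]
    support = e >= max(e_floor, 1e-300)
    z = np.zeros_like(e)
    z[support] = o[support] / e[support]
    if z.max() > 0:
        z = z / z.max()
    return NicheGrid(o=o, e=e, z=z, x_edges=x_edges, y_edges=y_edges,
                     range_id=range_id, bandwidth=bw)


# ---------------------------------------------------------------------------
# overlap and indices

def schoeners_d(z1, z2) -> float:
    """Schoener's D = 1 - 0.5 Σ|ẑ1 - ẑ2| on mass-normalized occupancy grids.

    0 = disjoint niches, 1 = identical niches; symmetric in its arguments.
    Accepts NicheGrid objects or raw arrays.
    """
    a = z1.z_hat if isinstance(z1, NicheGrid) else _norm_grid(z1)
    b = z2.z_hat if isinstance(z2, NicheGrid) else _norm_grid(z2)
    if a.shape != b.shape:
        raise ValueError("niche grids must share the same grid")
    return float(1.0 - 0.5 * np.abs(a - b).sum())


def _norm_grid(z) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    tot = z.sum()
    if tot == 0:
        raise ValueError("all-zero occupancy grid")
    return z / tot


def _occupied(z: np.ndarray, trunc_quantile: float) -> np.ndarray:
    """Cells counted as occupied: z above the kernel-tail truncation level."""
    pos = z[z > 0]
    if pos.size == 0:
        return z > 0
    cut = np.quantile(pos, trunc_quantile) if trunc_quantile > 0 else 0.0
    return z > cut


def niche_indices(z_native: NicheGrid, z_invaded: NicheGrid,
                  trunc_quantile: float = 0.05) -> tuple[float, float, float]:
    """(expansion, stability, unfilling) as percentages.

    Stability: % of invaded occupancy mass in environments also occupied in
    the native range; expansion: % in environments the native range does not
    occupy (expansion + stability = 100). Unfilling: % of native occupancy
    mass in environments unoccupied by the invaded range. Densities below the
    ``trunc_quantile`` quantile of positive values are treated as kernel tail
    leakage, not occupancy.
    """
    zn_occ = _occupied(z_native.z, trunc_quantile)
    zi_occ = _occupied(z_invaded.z, trunc_quantile)
    zi_hat = z_invaded.z_hat
    zn_hat = z_native.z_hat
    stability = 100.0 * zi_hat[zn_occ].sum()
    expansion = 100.0 - stability
    unfilling = 100.0 * zn_hat[~zi_occ].sum()
    return float(expansion), float(stability), float(unfilling)


def centroid_shift(native: NicheGrid, invaded: NicheGrid
                   ) -> tuple[np.ndarray, np.ndarray]:
    """(occurrence-centroid shift, background-centre shift) in PC coordinates.

    The first vector joins the occurrence-density-weighted centroids of the
    native and invaded niches; the second joins the availability-weighted
    centres of the two background environments.
    """
    occ_shift = invaded.centroid(invaded.o) - native.centroid(native.o)
    bg_shift = invaded.centroid(invaded.e) - native.centroid(native.e)
    return occ_shift, bg_shift


# ---------------------------------------------------------------------------
# similarity test

def similarity_test(native: NicheGrid, invaded: NicheGrid,
                    n_perm: int = 999, seed: int | None = None,
                    trunc_quantile: float = 0.05) -> tuple[float, np.ndarray]:
    """One-sided niche-similarity permutation test.

    Null model: the invaded occupancy grid is translated so that its centre
    lands on a cell chosen uniformly from the invaded background envelope
    (cells with e > 0); overlap D with the native niche is recomputed for each
    of ``n_perm`` relocations. The p-value (1 + #{D_sim >= D_obs}) /
    (n_perm + 1) asks whether the invaded niche is *more similar* to the
    native niche than such random placements.
    """
    rng = np.random.default_rng(seed)
    env_cells = np.argwhere(invaded.e > 0)
    if len(env_cells) < 2:
        raise ValueError("degenerate invaded background envelope")
    d_obs = schoeners_d(native, invaded)

    z = invaded.z
    nz = np.argwhere(z > 0)
    center = np.round(nz.mean(axis=0)).astype(int) if len(nz) else np.array([0, 0])
    zn_hat = native.z_hat
    d_sim = np.empty(n_perm)
    R, C = z.shape
    for k in range(n_perm):
        tr, tc = env_cells[rng.integers(len(env_cells))]
        dr, dc = tr - center[0], tc - center[1]
        shifted = np.zeros_like(z)
        r0, r1 = max(0, dr), min(R, R + dr)
        c0, c1 = max(0, dc), min(C, C + dc)
        shifted[r0:r1, c0:c1] = z[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
        tot = shifted.sum()
        if tot == 0:
            d_sim[k] = 0.0
            continue
        d_sim[k] = 1.0 - 0.5 * np.abs(zn_hat - shifted / tot).sum()
    p = (1.0 + np.sum(d_sim >= d_obs)) / (n_perm + 1.0)
    return float(p), d_sim


# ---------------------------------------------------------------------------
# one-call comparison

@dataclass
class NicheComparison:
    D: float
    expansion: float
    stability: float
    unfilling: float
    occurrence_centroid_shift: np.ndarray
    background_center_shift: np.ndarray
    similarity_p: float
    n_permutations: int

    def to_dict(self) -> dict:
        return {"schoeners_D": self.D, "expansion_pct": self.expansion,
                "stability_pct": self.stability, "unfilling_pct": self.unfilling,
                "occurrence_centroid_shift": self.occurrence_centroid_shift.tolist(),
                "background_center_shift": self.background_center_shift.tolist(),
                "similarity_p": self.similarity_p,
                "n_permutations": self.n_permutations}


def compare_niches(native_occ_env, native_bg_env, invaded_occ_env,
                   invaded_bg_env, R: int = 100, n_perm: int = 999,
                   seed: int | None = None) -> NicheComparison:
    """Full PCA-env comparison between a native and an invaded range."""
    axes = pca_env(native_bg_env, invaded_bg_env)
    bg_n = axes.scores(native_bg_env)
    bg_i = axes.scores(invaded_bg_env)
    pooled = np.vstack([bg_n, bg_i])
    lo, hi = pooled.min(axis=0), pooled.max(axis=0)
    pad = 0.05 * (hi - lo)
    bounds = (np.linspace(lo[0] - pad[0], hi[0] + pad[0], R + 1),
              np.linspace(lo[1] - pad[1], hi[1] + pad[1], R + 1))
    gn = density_grid(axes.scores(native_occ_env), bg_n, bounds, R, "native")
    gi = density_grid(axes.scores(invaded_occ_env), bg_i, bounds, R, "invaded")
    d = schoeners_d(gn, gi)
    exp_, stab, unf = niche_indices(gn, gi)
    occ_shift, bg_shift = centroid_shift(gn, gi)
    p, _ = similarity_test(gn, gi, n_perm=n_perm, seed=seed)
    return NicheComparison(D=d, expansion=exp_, stability=stab, unfilling=unf,
                           occurrence_centroid_shift=occ_shift,
                           background_center_shift=bg_shift,
                           similarity_p=p, n_permutations=n_perm)
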