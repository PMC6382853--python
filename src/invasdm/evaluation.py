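"""Model evaluation: discrimination, accuracy, and climate-analogy masking.

Because the models are presence-background (not presence-absence), background
points stand in as the negative class everywhere here: AUC is the probability
that a random presence outscores a random *background* point, and TSS treats
background as absence. Every report carries the background prevalence so the
metrics cannot be misread as presence-absence accuracy.

MESS (multivariate environmental similarity surface) measures, per cell, how
far the cell's climate sits outside the reference (training background)
distribution; cells with similarity > 0 are "analogous" and are the only ones
used when scoring a historical model against future records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .raster import RasterStack

__all__ = ["ConfusionCounts", "EvalResult", "MessSurface", "auc", "tss_max",
           "mess", "evaluate", "evaluate_forecast", "train_test_split_pb"]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else np.nan

    @property
    def tnr(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else np.nan

    @property
    def tss(self) -> float:
        return self.tpr + self.tnr - 1.0


@dataclass
class EvalResult:
    """Metrics for one model run; background is the negative class."""

    auc_train: float
    auc_test: float
    tss: float
    tss_threshold: float
    confusion: ConfusionCounts | None
    n_presence_test: int
    n_background_test: int

    @property
    def background_prevalence(self) -> float:
        tot = self.n_presence_test + self.n_background_test
        return self.n_background_test / tot if tot else np.nan

    def to_dict(self) -> dict:
        return {"auc_train": self.auc_train, "auc_test": self.auc_test,
                "tss": self.tss, "tss_threshold": self.tss_threshold,
                "n_presence_test": self.n_presence_test,
                "n_background_test": self.n_background_test,
                "background_prevalence": self.background_prevalence,
                "negative_class": "background"}


# ---------------------------------------------------------------------------
# discrimination / accuracy

def auc(presence_scores, background_scores) -> float:
    """Rank-based AUC: P(presence score > background score), ties half.

    Equivalent to the normalized Mann-Whitney U statistic.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("auc needs non-empty presence and background scores")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[:p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def tss_max(presence_scores, background_scores,
            thresholds=None) -> tuple[float, float, ConfusionCounts]:
    """Maximize TSS = TPR + TNR - 1 over a threshold grid.

    The default grid is the midpoints between consecutive distinct scores
    (clipped to [0, 1] for cloglog scores); the smallest maximizing threshold
    is returned. A point scores "presence" when score >= threshold.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("tss_max needs non-empty scores")
    if thresholds is None:
        s = np.unique(np.concatenate([p, b]))
        mids = (s[:-1] + s[1:]) / 2.0 if s.size > 1 else np.array([s[0]])
        lo, hi = min(0.0, s[0]), max(1.0, s[-1])
        thresholds = np.unique(np.clip(
            np.concatenate([[s[0] - 1e-9], mids, [s[-1] + 1e-9]]), lo, hi))
    thresholds = np.asarray(thresholds, dtype=float)
    tp = (p[:, None] >= thresholds[None, :]).sum(axis=0)
    fp = (b[:, None] >= thresholds[None, :]).sum(axis=0)
    fn = p.size - tp
    tn = b.size - fp
    tss = tp / p.size + tn / b.size - 1.0
    best = int(np.argmax(tss))          # argmax returns the first (smallest)
    cc = ConfusionCounts(tp=int(tp[best]), fp=int(fp[best]), tn=int(tn[best]),
                         fn=int(fn[best]), threshold=float(thresholds[best]))
    return float(tss[best]), float(thresholds[best]), cc


def train_test_split_pb(Xp, Xb, test_fraction: float = 0.2, seed: int = 0):
    """Label-stratified presence/background split (default 80/20)."""
    rng = np.random.default_rng(seed)
    Xp, Xb = np.asarray(Xp, float), np.asarray(Xb, float)
    ip = rng.permutation(len(Xp))
    ib = rng.permutation(len(Xb))
    np_test = max(1, int(round(test_fraction * len(Xp))))
    nb_test = max(1, int(round(test_fraction * len(Xb))))
    return (Xp[ip[np_test:]], Xb[ib[nb_test:]],
            Xp[ip[:np_test]], Xb[ib[:nb_test]])


def evaluate(model, Xp_train, Xb_train, Xp_test, Xb_test) -> EvalResult:
    """AUC-train, AUC-test and maximized TSS for a fitted suitability model."""
    sc = model.predict
    auc_tr = auc(sc(Xp_train), sc(Xb_train))
    p_test, b_test = sc(Xp_test), sc(Xb_test)
    auc_te = auc(p_test, b_test)
    tss, thr, cc = tss_max(p_test, b_test)
    return EvalResult(auc_train=auc_tr, auc_test=auc_te, tss=tss,
                      tss_threshold=thr, confusion=cc,
                      n_presence_test=len(p_test),
                      n_background_test=len(b_test))


# ---------------------------------------------------------------------------
# MESS

@dataclass
class MessSurface:
    similarity: np.ndarray           # per-cell min-over-variables similarity
    most_dissimilar: np.ndarray      # per-cell variable index (-1 = nodata)
    variables: list[str]
    stack: RasterStack | None = field(default=None, repr=False)

    @property
    def analogous(self) -> np.ndarray:
        """Boolean analogous-climate mask: similarity strictly > 0."""
        return self.similarity > 0

    def analogous_at(self, lon, lat) -> np.ndarray:
        if self.stack is None:
            raise ValueError("MESS surface has no georeferencing")
        r, c = self.stack.lonlat_to_rowcol(lon, lat)
        sim = self.similarity[r, c]
        return ~np.isnan(sim) & (sim > 0)


def mess_similarity(reference: np.ndarray, target: np.ndarray) -> np.ndarray:
    """MESS similarity of target values to one variable's reference sample.

    With f the percent of reference values strictly below the target value p,
    and (minv, maxv) the reference range:

        f = 0            -> (p - minv) / (maxv - minv) * 100
        0 < f <= 50      -> 2 f
        50 < f < 100     -> 2 (100 - f)
        f = 100          -> (maxv - p) / (maxv - minv) * 100

    Negative values mean the target lies outside the reference range.
    """
    ref = np.sort(np.asarray(reference, dtype=float))
    if ref.size < 2:
        raise ValueError("MESS reference needs at least 2 points per variable")
    minv, maxv = ref[0], ref[-1]
    if maxv <= minv:
        raise ValueError("zero-range reference variable")
    p = np.asarray(target, dtype=float)
    f = 100.0 * np.searchsorted(ref, p, side="left") / ref.size
    s = np.where(f == 0, (p - minv) / (maxv - minv) * 100.0,
         np.where(f <= 50, 2.0 * f,
          np.where(f < 100, 2.0 * (100.0 - f),
                   (maxv - p) / (maxv - minv) * 100.0)))
    return np.where(np.isnan(p), np.nan, s)


def mess(reference_env: np.ndarray, target_stack: RasterStack,
         variable_names: list[str] | None = None) -> MessSurface:
    """Multivariate environmental similarity of a stack to reference points.

    ``reference_env`` holds the training background environments, one column
    per variable (column order = ``variable_names`` or the stack's variables).
    The cell similarity is the minimum over variables and the most-dissimilar
    variable is the argmin.
    """
    names = variable_names or list(target_stack.variables)
    ref = np.asarray(reference_env, dtype=float)
    if ref.ndim != 2 or ref.shape[1] != len(names):
        raise ValueError("reference_env must be (n_points, n_variables)")
    rows, cols = target_stack.valid_rowcol()
    sims = np.empty((len(names), len(rows)))
    for k, name in enumerate(names):
        sims[k] = mess_similarity(ref[:, k], target_stack.band(name)[rows, cols])
    sim_grid = np.full(target_stack.shape, np.nan)
    var_grid = np.full(target_stack.shape, -1, dtype=int)
    sim_grid[rows, cols] = sims.min(axis=0)
    var_grid[rows, cols] = np.argmin(sims, axis=0)
    return MessSurface(similarity=sim_grid, most_dissimilar=var_grid,
                       variables=names, stack=target_stack)


# ---------------------------------------------------------------------------
# forecast evaluation

def evaluate_forecast(model, future_presence_env: np.ndarray,
                      background_env: np.ndarray,
                      presence_lonlat: tuple[np.ndarray, np.ndarray],
                      background_lonlat: tuple[np.ndarray, np.ndarray],
                      mess_surface: MessSurface) -> EvalResult:
    """Score a historical model against future records in analogous climate.

    Only future presences and background points whose cells have MESS
    similarity > 0 enter the metrics; evaluating a model in novel climate
    would conflate extrapolation error with forecast skill.
    """
    keep_p = mess_surface.analogous_at(*presence_lonlat)
    keep_b = mess_surface.analogous_at(*background_lonlat)
    if keep_p.sum() == 0:
        raise ValueError("no future presences fall in analogous climate; "
                         "forecast metrics are undefined")
    if keep_b.sum() == 0:
        raise ValueError("no background points fall in analogous climate")
    p_sc = model.predict(np.asarray(future_presence_env, float)[keep_p])
    b_sc = model.predict(np.asarray(background_env, float)[keep_b])
    a = auc(p_sc, b_sc)
    tss, thr, cc = tss_max(p_sc, b_sc)
    return EvalResult(auc_train=np.nan, auc_test=a, tss=tss, tss_threshold=thr,
                      confusion=cc, n_presence_test=int(keep_p.sum()),
                      n_background_test=int(keep_b.sum()))
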