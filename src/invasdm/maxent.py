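"""Presence-background maximum-entropy suitability model.

The model is the Gibbs density over environmental feature space,
``q(x) ∝ exp(λ·f(x))``, normalized over a background sample of the available
environment. Fitting maximizes the L1-penalized gain

    G(λ) = mean_presence[λ·f] − log mean_background[exp(λ·f)] − Σ_j β_j |λ_j|

with per-feature penalties ``β_j = β_mult · s_j / √m`` (``s_j`` the feature's
SD over presences, ``m`` the number of presences). Optimization is cyclic
coordinate descent: a damped Newton step with soft-thresholding per feature,
which also yields the per-feature gain trace used for variable contributions.

Outputs follow the cloglog convention: with ``H`` the entropy of the fitted
background distribution, ``cloglog = 1 − exp(−e^H · raw)``, interpretable as a
probability of presence under a typical-prevalence assumption.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .features import ALL_CLASSES, Feature, FeatureSet, build_features
from .raster import RasterStack

__all__ = ["MaxentSDM", "Prediction", "project", "variable_contributions",
           "limiting_factor", "fit_replicates"]


@dataclass
class Prediction:
    """Model projection onto a raster grid."""

    raw: np.ndarray       # normalized over training background; NaN = nodata
    cloglog: np.ndarray   # in [0, 1]; NaN = nodata
    stack: RasterStack


class MaxentSDM(BaseEstimator):
    """Maximum-entropy presence-background species distribution model.

    Parameters
    ----------
    beta_multiplier : float, default=3.0
        Global multiplier on the per-feature L1 penalties (the Maxent
        "betamultiplier"). Larger values give sparser, flatter models.
    feature_classes : tuple of str
        Subset of {"linear", "quadratic", "product", "hinge", "threshold"}.
    n_knots : int, default=9
        Interior quantile knots per variable for hinge/threshold features
        (9 = deciles).
    tol : float, default=1e-6
        Convergence threshold on the penalized gain change per full pass.
    max_iter : int, default=500
        Maximum number of full coordinate passes.
    sd_floor : float, default=1e-3
        Lower bound on the presence SD used in β_j, so features that are
        constant over presences remain (weakly) regularized.

    Attributes
    ----------
    feature_set_ : FeatureSet
    lambda_ : ndarray of feature weights
    beta_ : ndarray of per-feature penalties
    log_partition_ : float, log Σ_background exp(λ·f)
    entropy_ : float, entropy of the fitted background distribution
    gain_ : float, final penalized gain
    gain_trace_ : list of (feature index, gain increment)
    converged_ : bool
    """

    def __init__(self, beta_multiplier: float = 3.0,
                 feature_classes: tuple[str, ...] = ALL_CLASSES,
                 n_knots: int = 9, tol: float = 1e-6, max_iter: int = 500,
                 sd_floor: float = 1e-3):
        self.beta_multiplier = beta_multiplier
        self.feature_classes = feature_classes
        self.n_knots = n_knots
        self.tol = tol
        self.max_iter = max_iter
        self.sd_floor = sd_floor

    # -- fitting ------------------------------------------------------------
    def fit(self, X, y, variable_names: list[str] | None = None):
        """Fit to presence (y=1) and background (y=0) environmental rows."""
        X, names = _as_matrix(X, variable_names)
        y = np.asarray(y).astype(int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("y must be binary: 1 = presence, 0 = background")
        Xp, Xb = X[y == 1], X[y == 0]
        if len(Xp) < 2 or len(Xb) < 2:
            raise ValueError("need at least 2 presence and 2 background rows")
        return self._fit_split(Xp, Xb, names)

    def fit_presence_background(self, X_presence, X_background,
                                variable_names: list[str] | None = None):
        """Fit from separate presence and background matrices."""
        Xp, names = _as_matrix(X_presence, variable_names)
        Xb, _ = _as_matrix(X_background, names)
        return self._fit_split(Xp, Xb, names)

    def _fit_split(self, Xp, Xb, names):

        self.variable_names_ = names
        self.feature_set_ = build_features(
            np.vstack([Xp, Xb]), names, classes=tuple(self.feature_classes),
            n_knots=self.n_knots)
        kept = [names.index(n) for n in self.feature_set_.variable_names]
        self.presence_variable_means_ = Xp[:, kept].mean(axis=0)

        Fp = self.feature_set_.transform(Xp[:, kept])
        Fb = self.feature_set_.transform(Xb[:, kept])
        self._coordinate_descent(Fp, Fb)
        self.n_presence_, self.n_background_ = len(Xp), len(Xb)
        self.n_features_in_ = Xp.shape[1]
        return self

    def _coordinate_descent(self, Fp: np.ndarray, Fb: np.ndarray) -> None:
        m, J = Fp.shape
        n = Fb.shape[0]
        pbar = Fp.mean(axis=0)
        sd = np.maximum(Fp.std(axis=0), self.sd_floor)
        beta = self.beta_multiplier * sd / np.sqrt(m)

        lam = np.zeros(J)
        w = np.full(n, 1.0 / n)      # softmax weights over background
        gain = 0.0                   # penalized gain; 0 at λ = 0
        trace: list[tuple[int, float]] = []
        converged = False

        for it in range(self.max_iter):
            gain_at_pass_start = gain
            for j in range(J):
                fj = Fb[:, j]
                E = float(w @ fj)
                V = float(w @ (fj * fj)) - E * E
                V = max(V, 1e-10)
                g = pbar[j] - E
                a = lam[j] + g / V
                lam_new = np.sign(a) * max(abs(a) - beta[j] / V, 0.0)
                delta = float(np.clip(lam_new - lam[j], -1.0, 1.0))
                if delta == 0.0:
                    continue
                for _ in range(25):
                    lam_try = lam[j] + delta
                    factor = float(w @ np.exp(delta * fj))
                    dgain = (delta * pbar[j] - np.log(factor)
                             - beta[j] * (abs(lam_try) - abs(lam[j])))
                    if dgain >= -1e-12:
                        break
                    delta *= 0.5
                else:
                    continue
                if dgain <= 0.0:
                    continue
                lam[j] = lam[j] + delta
                w = w * np.exp(delta * fj) / factor
                gain += dgain
                trace.append((j, dgain))
            if (it + 1) % 25 == 0:
                # refresh weights from scratch to kill numerical drift
                s = Fb @ lam
                w = np.exp(s - logsumexp(s))
            if gain - gain_at_pass_start < self.tol:
                converged = True
                break

        s = Fb @ lam
        self.lambda_ = lam
        self.beta_ = beta
        self.log_partition_ = float(logsumexp(s))
        wfin = np.exp(s - self.log_partition_)
        pos = wfin > 0
        self.entropy_ = float(-(wfin[pos] * np.log(wfin[pos])).sum())
        self.gain_ = gain
        self.gain_trace_ = trace
        self.converged_ = converged
        self.n_iter_ = it + 1
        if not converged:
            import warnings
            warnings.warn("maxent coordinate descent did not converge; "
                          "returning the partial model")

    # -- prediction ----------------------------------------------------------
    def _scores(self, X) -> np.ndarray:
        kept = [self.variable_names_.index(n)
                for n in self.feature_set_.variable_names]
        X, _ = _as_matrix(X, self.variable_names_)
        F = self.feature_set_.transform(X[:, kept])
        return F @ self.lambda_

    def predict_raw(self, X) -> np.ndarray:
        """Gibbs density normalized over the training background (sums to 1
        across the training background sample)."""
        return np.exp(self._scores(X) - self.log_partition_)

    def predict(self, X) -> np.ndarray:
        """Cloglog suitability in [0, 1]."""
        return self.cloglog(self.predict_raw(X))

    def cloglog(self, raw: np.ndarray) -> np.ndarray:
        return 1.0 - np.exp(-np.exp(self.entropy_) * raw)

    # -- persistence ----------------------------------------------------------
    def to_json(self) -> str:
        fs = self.feature_set_
        payload = {
            "params": self.get_params(),
            "variable_names": self.variable_names_,
            "feature_variables": fs.variable_names,
            "bounds": {k: list(v) for k, v in fs.bounds.items()},
            "features": [{"kind": f.kind, "variables": list(f.variables),
                          "knot": f.knot, "reverse": f.reverse}
                         for f in fs.features],
            "lambda": self.lambda_.tolist(),
            "beta": self.beta_.tolist(),
            "log_partition": self.log_partition_,
            "entropy": self.entropy_,
            "gain": self.gain_,
            "presence_variable_means": self.presence_variable_means_.tolist(),
            "n_presence": self.n_presence_,
            "n_background": self.n_background_,
            "converged": self.converged_,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MaxentSDM":
        d = json.loads(text)
        model = cls(**d["params"])
        model.variable_names_ = d["variable_names"]
        model.feature_set_ = FeatureSet(
            variable_names=d["feature_variables"],
            features=[Feature(f["kind"], tuple(f["variables"]), f["knot"],
                              f["reverse"]) for f in d["features"]],
            bounds={k: tuple(v) for k, v in d["bounds"].items()})
        model.lambda_ = np.asarray(d["lambda"])
        model.beta_ = np.asarray(d["beta"])
        model.log_partition_ = d["log_partition"]
        model.entropy_ = d["entropy"]
        model.gain_ = d["gain"]
        model.presence_variable_means_ = np.asarray(d["presence_variable_means"])
        model.n_presence_ = d["n_presence"]
        model.n_background_ = d["n_background"]
        model.converged_ = d["converged"]
        model.gain_trace_ = []
        return model


def _as_matrix(X, variable_names):
    """Accept a DataFrame or array; return (array, names)."""
    if hasattr(X, "columns"):
        names = list(X.columns)
        return X.to_numpy(dtype=float), names
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n_points, n_variables)")
    if variable_names is None:
        variable_names = [f"x{i}" for i in range(X.shape[1])]
    if len(variable_names) != X.shape[1]:
        raise ValueError("variable_names length mismatch")
    return X, list(variable_names)


# ---------------------------------------------------------------------------
# projection and attribution

def project(model: MaxentSDM, stack: RasterStack) -> Prediction:
    """Project a fitted model onto a raster stack (clamped to training range)."""
    names = model.feature_set_.variable_names
    missing = [v for v in names if v not in stack.variables]
    if missing:
        raise KeyError(f"stack is missing model variables: {missing}")
    rows, cols = stack.valid_rowcol()
    X = np.stack([stack.band(v)[rows, cols] for v in names], axis=1)
    F = model.feature_set_.transform(X)
    raw_pts = np.exp(F @ model.lambda_ - model.log_partition_)
    raw = np.full(stack.shape, np.nan)
    clog = np.full(stack.shape, np.nan)
    raw[rows, cols] = raw_pts
    clog[rows, cols] = model.cloglog(raw_pts)
    return Prediction(raw=raw, cloglog=clog, stack=stack)


def variable_contributions(model: MaxentSDM) -> dict[str, float]:
    """Percent contribution of each variable, from the optimization trace.

    Each accepted coordinate step's gain increment is credited to the updated
    feature's source variable (product features split the credit evenly
    between their two variables). Negative variable totals are floored at 0
    and the result is normalized to sum to 100.
    """
    fs = model.feature_set_
    totals = {name: 0.0 for name in fs.variable_names}
    if not model.gain_trace_:
        raise ValueError("model has no optimization trace; refit with "
                         "MaxentSDM or use permutation_importance")
    for j, dgain in model.gain_trace_:
        srcs = fs.source_variables(j)
        for v in srcs:
            totals[v] += dgain / len(srcs)
    vals = np.array([max(totals[v], 0.0) for v in fs.variable_names])
    if vals.sum() == 0:
        vals = np.ones_like(vals)
    vals = 100.0 * vals / vals.sum()
    return dict(zip(fs.variable_names, vals.tolist()))


def permutation_importance(model: MaxentSDM, X_presence, X_background,
                           seed: int | None = None) -> dict[str, float]:
    """Fallback attribution when no trace is available: drop in training AUC
    when one variable's values are permuted, normalized to 100."""
    from .evaluation import auc
    rng = np.random.default_rng(seed)
    Xp, names = _as_matrix(X_presence, getattr(model, "variable_names_", None))
    Xb, _ = _as_matrix(X_background, names)
    base = auc(model.predict_raw(Xp), model.predict_raw(Xb))
    drops = {}
    for name in model.feature_set_.variable_names:
        j = names.index(name)
        Xpp, Xbp = Xp.copy(), Xb.copy()
        allv = np.concatenate([Xpp[:, j], Xbp[:, j]])
        rng.shuffle(allv)
        Xpp[:, j] = allv[:len(Xpp)]
        Xbp[:, j] = allv[len(Xpp):]
        drops[name] = max(base - auc(model.predict_raw(Xpp),
                                     model.predict_raw(Xbp)), 0.0)
    tot = sum(drops.values()) or 1.0
    return {k: 100.0 * v / tot for k, v in drops.items()}


def limiting_factor(model: MaxentSDM, stack: RasterStack) -> np.ndarray:
    """Per-cell index of the variable limiting predicted suitability most.

    For each cell and each variable v, the cloglog prediction is recomputed
    with v replaced by its mean over the presence training points; the
    limiting factor is the variable whose replacement raises the prediction
    the most (ties broken by variable order). Masked cells hold -1.
    """
    names = model.feature_set_.variable_names
    rows, cols = stack.valid_rowcol()
    order = [stack.variables.index(v) for v in names]
    X = stack.values[:, rows, cols].T[:, order]
    base = _cloglog_for(model, X)
    deltas = np.empty((len(names), len(base)))
    for k, name in enumerate(names):
        X_alt = X.copy()
        X_alt[:, k] = model.presence_variable_means_[k]
        deltas[k] = _cloglog_for(model, X_alt) - base
    winner = np.argmax(deltas, axis=0)   # argmax takes the first max: tie rule
    out = np.full(stack.shape, -1, dtype=int)
    out[rows, cols] = winner
    return out


def _cloglog_for(model: MaxentSDM, X_kept: np.ndarray) -> np.ndarray:
    F = model.feature_set_.transform(X_kept)
    raw = np.exp(F @ model.lambda_ - model.log_partition_)
    return model.cloglog(raw)


# ---------------------------------------------------------------------------
# replicated cross-validated fits

def fit_replicates(X_presence, X_background, variable_names=None,
                   n_folds: int = 5, n_reps: int = 5, seed: int = 0,
                   **model_kw):
    """Seeded repetitions of a k-fold presence partition (default 5 x 5 = 25
    fits). Returns a list of (model, eval_result); metrics and projections are
    conventionally averaged over the fits."""
    from .evaluation import evaluate
    Xp, names = _as_matrix(X_presence, variable_names)
    Xb, _ = _as_matrix(X_background, names)
    results = []
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + rep)
        fold_p = rng.permutation(len(Xp)) % n_folds
        fold_b = rng.permutation(len(Xb)) % n_folds
        for fold in range(n_folds):
            model = MaxentSDM(**model_kw)
            model.fit_presence_background(Xp[fold_p != fold], Xb[fold_b != fold],
                                          names)
            res = evaluate(model, Xp[fold_p != fold], Xb[fold_b != fold],
                           Xp[fold_p == fold], Xb[fold_b == fold])
            results.append((model, res))
    return results


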