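"""Feature expansion for maximum-entropy suitability modelling.

Raw environmental variables are expanded into the classic Maxent feature
classes — linear, quadratic, product, hinge and threshold — each normalized to
[0, 1] using the training min/max. Hinge and threshold knots are placed at the
training deciles of each variable (both hinge orientations are generated).
Values outside the training range are clamped before transformation, which is
what keeps projections onto novel (e.g. future) climates bounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALL_CLASSES = ("linear", "quadratic", "product", "hinge", "threshold")


@dataclass
class Feature:
    kind: str                 # one of ALL_CLASSES
    variables: tuple[str, ...]
    knot: float | None = None
    reverse: bool = False     # hinge orientation


@dataclass
class FeatureSet:
    """Feature definitions plus the normalization bounds that fix their scale."""

    variable_names: list[str]
    features: list[Feature]
    bounds: dict[str, tuple[float, float]]  # training min/max per variable
    dropped: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)

    def _norm(self, X: np.ndarray) -> np.ndarray:
        """Clamp to training bounds, scale each variable to [0, 1]."""
        out = np.empty_like(X, dtype=float)
        for j, name in enumerate(self.variable_names):
            lo, hi = self.bounds[name]
            out[:, j] = (np.clip(X[:, j], lo, hi) - lo) / (hi - lo)
        return out

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Feature matrix, shape (n_points, n_features), values in [0, 1].

        ``X`` columns follow ``variable_names`` order.
        """
        X = np.asarray(X, dtype=float)
        Z = self._norm(X)
        col = {name: i for i, name in enumerate(self.variable_names)}
        cols = []
        for f in self.features:
            if f.kind == "linear":
                cols.append(Z[:, col[f.variables[0]]])
            elif f.kind == "quadratic":
                cols.append(Z[:, col[f.variables[0]]] ** 2)
            elif f.kind == "product":
                cols.append(Z[:, col[f.variables[0]]] * Z[:, col[f.variables[1]]])
            elif f.kind == "hinge":
                z = Z[:, col[f.variables[0]]]
                k = f.knot
                if f.reverse:
                    denom = max(k, 1e-12)
                    cols.append(np.clip((k - z) / denom, 0.0, 1.0))
                else:
                    denom = max(1.0 - k, 1e-12)
                    cols.append(np.clip((z - k) / denom, 0.0, 1.0))
            elif f.kind == "threshold":
                cols.append((Z[:, col[f.variables[0]]] > f.knot).astype(float))
            else:  # pragma: no cover
                raise ValueError(f"unknown feature kind {f.kind!r}")
        return np.column_stack(cols) if cols else np.empty((len(X), 0))

    def source_variables(self, j: int) -> tuple[str, ...]:
        return self.features[j].variables


def build_features(X_train: np.ndarray, variable_names: list[str],
                   classes: tuple[str, ...] = ALL_CLASSES,
                   n_knots: int = 9) -> FeatureSet:
    """Define the feature set from training data (presence + background).

    Knots for hinge/threshold features sit at the ``n_knots`` interior
    quantiles of each (normalized) variable — deciles by default. Constant
    variables cannot be normalized and are dropped with a warning.
    """
    X_train = np.asarray(X_train, dtype=float)
    if X_train.shape[0] < 2:
        raise ValueError("need at least 2 training points")
    unknown = set(classes) - set(ALL_CLASSES)
    if unknown:
        raise ValueError(f"unknown feature classes: {sorted(unknown)}")

    bounds, keep, dropped = {}, [], []
    for j, name in enumerate(variable_names):
        lo, hi = float(np.nanmin(X_train[:, j])), float(np.nanmax(X_train[:, j]))
        if hi <= lo:
            dropped.append(name)
            continue
        bounds[name] = (lo, hi)
        keep.append(name)
    if dropped:
        import warnings
        warnings.warn(f"constant variables dropped from features: {dropped}")

    fs = FeatureSet(variable_names=keep, features=[], bounds=bounds,
                    dropped=dropped)
    Z = fs._norm(X_train[:, [variable_names.index(n) for n in keep]])
    qs = np.linspace(0, 1, n_knots + 2)[1:-1]

    feats: list[Feature] = []
    for name in keep:
        if "linear" in classes:
            feats.append(Feature("linear", (name,)))
        if "quadratic" in classes:
            feats.append(Feature("quadratic", (name,)))
    if "product" in classes:
        for a in range(len(keep)):
            for b in range(a + 1, len(keep)):
                feats.append(Feature("product", (keep[a], keep[b])))
    for name in keep:
        z = Z[:, keep.index(name)]
        knots = np.quantile(z, qs)
        if "hinge" in classes:
            for k in knots:
                feats.append(Feature("hinge", (name,), knot=float(k), reverse=False))
                feats.append(Feature("hinge", (name,), knot=float(k), reverse=True))
        if "threshold" in classes:
            for k in knots:
                feats.append(Feature("threshold", (name,), knot=float(k)))
    fs.features = feats
    return fs
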