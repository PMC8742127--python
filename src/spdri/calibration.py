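"""Calibration of the K_norm-diameter line and of the beta surfaces.

Four stages, mirroring the analysis workflow:

1. per-property-set ordinary least squares of K_norm on the capillary
   diameter, yielding the intercept ``beta0`` and slope ``beta1``;
2. out-of-bag permuted predictor importance of the 24 optical-property
   predictors in a bagged tree ensemble, to find which properties drive
   ``beta0`` / ``beta1`` (the reduced scattering of the two outermost skin
   layers dominates);
3. hyperparameter-tuned ensemble regression (bagging or least-squares
   boosting, 500 learning cycles) of the response on the selected
   predictors;
4. a closed-form surface ``z = a1*exp(-b1*x1) + a2*exp(-b2*x2) + c`` fitted
   by multistart nonlinear least squares to the ensemble's response probed
   on a grid spanning the central 20-80% band of each predictor's range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import KFold

__all__ = [
    "LinearFit", "fit_knorm_regression",
    "ImportanceResult", "rank_predictors",
    "EnsembleModel", "tune_and_train",
    "AnalyticCalib", "fit_analytic_surface", "probe_model_surface",
    "DEFAULT_SLOPE_SURFACE", "DEFAULT_INTERCEPT_SURFACE",
]


# --------------------------------------------------------------------------
# K_norm-vs-diameter line
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearFit:
    """OLS line K_norm = beta0 + beta1 * diameter."""

    beta0: float           # intercept (px)
    beta1: float           # slope (px / um)
    r_squared: float
    n_used: int
    n_missing: int

    def predict(self, diameter_um) -> np.ndarray:
        return self.beta0 + self.beta1 * np.asarray(diameter_um, dtype=float)


class InvalidFitError(ValueError):
    pass


def fit_knorm_regression(pairs) -> LinearFit:
    """Fit the K_norm-vs-diameter line, skipping missing K_norm values.

    ``pairs`` is an iterable of (diameter_um, k_norm) with ``k_norm`` possibly
    None/NaN (a capillary whose extrema could not be located).
    """
    d, k, n_missing = [], [], 0
    for diam, val in pairs:
        if val is None or (isinstance(val, float) and np.isnan(val)):
            n_missing += 1
            continue
        d.append(float(diam))
        k.append(float(val))
    if len(d) < 2:
        raise InvalidFitError(
            f"need >= 2 non-missing K_norm values, got {len(d)}"
        )
    res = linregress(d, k)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    return LinearFit(beta0=float(res.intercept), beta1=float(res.slope),
                     r_squared=r2, n_used=len(d), n_missing=n_missing)


# --------------------------------------------------------------------------
# out-of-bag permuted predictor importance
# --------------------------------------------------------------------------

@dataclass
class ImportanceResult:
    names: tuple[str, ...]
    scores: np.ndarray          # one score per predictor
    ranking: tuple[str, ...]    # names sorted by decreasing score

    def top(self, k: int) -> tuple[str, ...]:
        return self.ranking[:k]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"predictor": self.names,
                             "importance": self.scores}
                            ).sort_values("importance", ascending=False,
                                          ignore_index=True)


def rank_predictors(X: np.ndarray, y: np.ndarray,
                    names: tuple[str, ...] | list[str] | None = None,
                    rng: np.random.Generator | int | None = None,
                    n_trees: int = 100) -> ImportanceResult:
    """Out-of-bag permuted predictor importance of a bagged tree ensemble.

    Every predictor is available at every split (no random subspace), as
    required for a valid importance estimate.  For each tree, the MSE on its
    out-of-bag rows is compared with the MSE after permuting one predictor
    among those rows; the importance is the mean error increase over trees
    divided by its standard deviation.  A constant response yields all-zero
    scores with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, p = X.shape
    if n < 30:
        raise ValueError(f"need >= 30 rows for a stable importance, got {n}")
    if np.isnan(X).any():
        raise ValueError("missing predictor values are not supported")
    if names is None:
        names = tuple(f"x{j}" for j in range(p))
    names = tuple(names)
    if len(names) != p:
        raise ValueError("one name per predictor required")
    gen = np.random.default_rng(rng)
    if np.ptp(y) == 0:
        warnings.warn("constant response: all importances are zero")
        return ImportanceResult(names=names, scores=np.zeros(p),
                                ranking=names)

    forest = RandomForestRegressor(
        n_estimators=n_trees, max_features=None, bootstrap=True,
        random_state=int(gen.integers(2**31 - 1)),
    )
    forest.fit(X, y)
    deltas = np.full((n_trees, p), np.nan)
    for t, tree in enumerate(forest.estimators_):
        inbag = forest.estimators_samples_[t]
        oob = np.setdiff1d(np.arange(n), inbag)
        if oob.size < 2:
            continue
        Xo = X[oob]
        yo = y[oob]
        base = np.mean((tree.predict(Xo) - yo) ** 2)
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xo[gen.permutation(oob.size), j]
            deltas[t, j] = np.mean((tree.predict(Xp) - yo) ** 2) - base
    mean = np.nanmean(deltas, axis=0)
    sd = np.nanstd(deltas, axis=0, ddof=1)
    scores = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), mean)
    order = np.argsort(scores)[::-1]
    return ImportanceResult(names=names, scores=scores,
                            ranking=tuple(names[i] for i in order))


# --------------------------------------------------------------------------
# tuned ensemble regression
# --------------------------------------------------------------------------

N_LEARNING_CYCLES = 500

_LEARNING_RATES = (0.05, 0.1, 0.35, 0.5)
_MIN_LEAVES = (1, 3, 5)


@dataclass
class EnsembleModel:
    """A trained bagging or least-squares-boosting tree ensemble."""

    method: str                       # "bagging" | "lsboost"
    n_cycles: int
    learning_rate: float | None
    min_leaf: int
    model: object
    cv_mse: float
    train_r2: float
    test_r2: float | None = None

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.model.predict(X)

    def save(self, path) -> None:
        """Serialize the trained ensemble plus a JSON metadata sidecar."""
        import json
        from pathlib import Path

        import joblib

        path = Path(path)
        joblib.dump(self.model, path)
        meta = {"format_version": 1, "method": self.method,
                "n_cycles": self.n_cycles,
                "learning_rate": self.learning_rate,
                "min_leaf": self.min_leaf, "cv_mse": self.cv_mse,
                "train_r2": self.train_r2, "test_r2": self.test_r2}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        import json
        from pathlib import Path

        import joblib

        path = Path(path)
        meta = json.loads(
            path.with_suffix(path.suffix + ".json").read_text())
        meta.pop("format_version", None)
        return cls(model=joblib.load(path), **meta)


def _make_estimator(method: str, lr: float | None, min_leaf: int,
                    n_cycles: int, seed: int):
    if method == "bagging":
        return RandomForestRegressor(
            n_estimators=n_cycles, max_features=None, bootstrap=True,
            min_samples_leaf=min_leaf, random_state=seed,
        )
    return GradientBoostingRegressor(
        loss="squared_error", n_estimators=n_cycles, learning_rate=lr,
        min_samples_leaf=min_leaf, random_state=seed,
    )


def tune_and_train(X: np.ndarray, y: np.ndarray,
                   rng: np.random.Generator | int | None = None,
                   n_cycles: int = N_LEARNING_CYCLES,
                   cv_folds: int = 5) -> EnsembleModel:
    """5-fold CV grid search over {bagging, LS-boosting} x rate x leaf size.

    The grid (learning rate in {0.05, 0.1, 0.35, 0.5}, minimum leaf size in
    {1, 3, 5}) is deterministic given the seed; the winning configuration is
    retrained on all rows with ``n_cycles`` learning cycles.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 30:
        raise ValueError(f"need >= 30 rows to tune, got {n}")
    gen = np.random.default_rng(rng)
    seed = int(gen.integers(2**31 - 1))
    folds = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(folds.split(X))
    for tr, te in splits:
        if te.size < 2:
            raise ValueError("degenerate cross-validation fold")

    configs: list[tuple[str, float | None, int]] = [
        ("bagging", None, leaf) for leaf in _MIN_LEAVES
    ] + [
        ("lsboost", lr, leaf)
        for lr, leaf in product(_LEARNING_RATES, _MIN_LEAVES)
    ]
    best: tuple[float, tuple[str, float | None, int]] | None = None
    for cfg in configs:
        mse = 0.0
        for tr, te in splits:
            est = _make_estimator(*cfg, n_cycles=n_cycles, seed=seed)
            est.fit(X[tr], y[tr])
            mse += np.mean((est.predict(X[te]) - y[te]) ** 2)
        mse /= len(splits)
        if best is None or mse < best[0]:
            best = (mse, cfg)
    assert best is not None
    cv_mse, (method, lr, leaf) = best
    final = _make_estimator(method, lr, leaf, n_cycles=n_cycles, seed=seed)
    final.fit(X, y)
    ss_res = np.sum((final.predict(X) - y) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    train_r2 = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else 0.0
    return EnsembleModel(method=method, n_cycles=n_cycles, learning_rate=lr,
                         min_leaf=leaf, model=final, cv_mse=float(cv_mse),
                         train_r2=train_r2)


# --------------------------------------------------------------------------
# analytic two-exponential calibration surface
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalyticCalib:
    """Surface z = a1*exp(-b1*x1) + a2*exp(-b2*x2) + c.

    ``x1``/``x2`` are the reduced scattering coefficients of the two
    outermost skin layers (mm^-1); ``c`` is the asymptote for strongly
    scattering surface layers.
    """

    a1: float
    b1: float
    a2: float
    b2: float
    c: float
    r_squared: float = 1.0
    response: str = ""          # "beta0" | "beta1" | free-form label

    def __call__(self, x1, x2) -> np.ndarray:
        x1 = np.asarray(x1, dtype=float)
        x2 = np.asarray(x2, dtype=float)
        return (self.a1 * np.exp(-self.b1 * x1)
                + self.a2 * np.exp(-self.b2 * x2) + self.c)

    @property
    def asymptote(self) -> float:
        """Limit for x1, x2 -> infinity (the exponential terms vanish)."""
        big = 1e9
        return float(self(big, big))

    def coefficients(self) -> np.ndarray:
        return np.array([self.a1, self.b1, self.a2, self.b2, self.c])


#: calibration surface for the slope beta1 of the K_norm-vs-diameter line as
#: a function of the reduced scattering of the two outermost skin layers
DEFAULT_SLOPE_SURFACE = AnalyticCalib(
    a1=1.251, b1=0.3319, a2=1.046, b2=0.6513, c=0.1389, response="beta1",
)

#: calibration surface for the intercept beta0
DEFAULT_INTERCEPT_SURFACE = AnalyticCalib(
    a1=-3.803, b1=0.4382, a2=-2.356, b2=0.6406, c=-0.4093, response="beta0",
)


class SurfaceFitError(RuntimeError):
    """Raised when the multistart nonlinear fit fails to converge."""

    def __init__(self, msg: str, best_residual: float):
        super().__init__(msg)
        self.best_residual = best_residual


def _solve_linear(x1, x2, z, b1, b2):
    """Given decay rates, the amplitudes and constant are linear in z."""
    M = np.column_stack([np.exp(-b1 * x1), np.exp(-b2 * x2), np.ones_like(x1)])
    coef, *_ = np.linalg.lstsq(M, z, rcond=None)
    resid = M @ coef - z
    return coef, float(resid @ resid)


def fit_analytic_surface(x1, x2, z, response: str = "",
                         decay_starts: tuple[float, ...] = (0.1, 0.5, 1.0),
                         ) -> AnalyticCalib:
    """Multistart nonlinear least squares of the two-exponential surface.

    The fit exploits the model's structure: for fixed decay rates (b1, b2)
    the amplitudes and the constant are solved linearly, so the multistart
    only scans a small decay-rate grid before polishing all five parameters
    with a bounded trust-region solver (b1, b2 > 0).  No interaction term is
    included.
    """
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if not (x1.size == x2.size == z.size):
        raise ValueError("x1, x2, z must have equal length")
    if x1.size < 10:
        raise ValueError("need >= 10 points to fit the surface")
    if np.ptp(x1) == 0 or np.ptp(x2) == 0:
        raise ValueError("points must span both predictor axes")

    # stage 1: decay-rate grid with linear amplitude solves
    best = None
    for b1 in decay_starts:
        for b2 in decay_starts:
            coef, ss = _solve_linear(x1, x2, z, b1, b2)
            if best is None or ss < best[0]:
                best = (ss, np.array([coef[0], b1, coef[1], b2, coef[2]]))
    assert best is not None

    def residual(p):
        return p[0] * np.exp(-p[1] * x1) + p[2] * np.exp(-p[3] * x2) + p[4] - z

    def jac(p):
        e1 = np.exp(-p[1] * x1)
        e2 = np.exp(-p[3] * x2)
        return np.column_stack([
            e1, -p[0] * x1 * e1, e2, -p[2] * x2 * e2, np.ones_like(x1)
        ])

    lb = [-np.inf, 1e-9, -np.inf, 1e-9, -np.inf]
    ub = [np.inf] * 5
    best_cost = np.inf
    best_p = None
    starts = [best[1]]
    # a couple of perturbed restarts guard against a shallow local minimum
    for f1 in (0.5, 2.0):
        p = best[1].copy()
        p[1] *= f1
        p[3] /= f1
        coef, _ = _solve_linear(x1, x2, z, p[1], p[3])
        p[0], p[2], p[4] = coef
        starts.append(p)
    for p0 in starts:
        p0 = np.clip(p0, lb, ub)
        try:
            sol = least_squares(residual, p0, jac=jac, bounds=(lb, ub),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if sol.cost < best_cost:
            best_cost = sol.cost
            best_p = sol.x
    if best_p is None:
        raise SurfaceFitError("surface fit failed to converge",
                              best_residual=float(np.sqrt(2 * best[0])))
    resid = residual(best_p)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((z - z.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return AnalyticCalib(a1=float(best_p[0]), b1=float(best_p[1]),
                         a2=float(best_p[2]), b2=float(best_p[3]),
                         c=float(best_p[4]), r_squared=float(r2),
                         response=response)


def probe_model_surface(model, x1_values: np.ndarray, x2_values: np.ndarray,
                        n_points: int = 200,
                        band: tuple[float, float] = (0.2, 0.8),
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Query a trained model on a grid inside the central band of each range.

    ``n_points`` equidistant values are generated per predictor between 20%
    and 80% of its observed min-max range (outlier exclusion); the model is
    evaluated on the full grid.  Returns flat (x1, x2, z) arrays.
    """
    x1_values = np.asarray(x1_values, dtype=float)
    x2_values = np.asarray(x2_values, dtype=float)

    def band_points(v):
        lo, hi = v.min(), v.max()
        return np.linspace(lo + band[0] * (hi - lo),
                           lo + band[1] * (hi - lo), n_points)

    g1 = band_points(x1_values)
    g2 = band_points(x2_values)
    X1, X2 = np.meshgrid(g1, g2, indexing="ij")
    pts = np.column_stack([X1.ravel(), X2.ravel()])
    z = np.asarray(model.predict(pts), dtype=float)
    return pts[:, 0], pts[:, 1], z
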