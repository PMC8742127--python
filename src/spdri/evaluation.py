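"""Diameter prediction and its error statistics.

A measured ``K_norm`` converts to an absolute capillary diameter through the
inverted calibration line::

    diameter = (K_norm - beta0) / beta1

The evaluation repeats an 80/20 split of the property sets: the calibration
models (tree ensemble, analytic surface) are trained on 80% of the rows,
``beta0``/``beta1`` are predicted for the held-out rows, every held-out
``K_norm`` value is converted to a diameter, and the error is summarised as
mean / median / sample SD / coefficient of variation per true diameter.  A
third, fixed-value mode uses the betas of the unperturbed ideal property set
for every row, quantifying what calibration-free operation would cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import (
    _make_estimator,
    fit_analytic_surface,
    probe_model_surface,
    tune_and_train,
)
from .surrogate import CalibrationDataset

METHODS = ("rf", "analytic", "fixed")

#: slopes with magnitude below this are treated as degenerate
BETA1_TOLERANCE = 1e-9


class DegenerateSlopeError(ZeroDivisionError):
    pass


def predict_diameter(knorm, beta0, beta1,
                     tolerance: float = BETA1_TOLERANCE):
    """Invert the calibration line: (K_norm - beta0) / beta1, um."""
    beta1 = np.asarray(beta1, dtype=float)
    if np.any(np.abs(beta1) <= tolerance):
        raise DegenerateSlopeError(
            f"|beta1| <= {tolerance}: the calibration line is degenerate"
        )
    out = (np.asarray(knorm, dtype=float) - np.asarray(beta0, dtype=float)) / beta1
    return out if out.ndim else float(out)


@dataclass
class SummaryTable:
    """Per (method x diameter) error statistics plus an overall CV per method."""

    frame: pd.DataFrame            # method, diameter, mean, median, sd, cv_percent
    overall_cv_percent: dict[str, float]
    n_invalid: dict[str, int]      # excluded predictions (non-positive slope)
    pooled: bool = False

    def cell(self, method: str, diameter: float) -> pd.Series:
        sel = self.frame[(self.frame["method"] == method)
                         & (np.isclose(self.frame["diameter"], diameter))]
        if sel.empty:
            raise KeyError((method, diameter))
        return sel.iloc[0]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def summarize(records: pd.DataFrame, min_per_cell: int = 2) -> SummaryTable:
    """Mean / median / sample SD / CV per (method, true diameter).

    ``records`` needs the columns ``method``, ``true_diameter`` and
    ``predicted_diameter``.  Cells with fewer than ``min_per_cell`` records
    are flagged and excluded from the table.
    """
    need = {"method", "true_diameter", "predicted_diameter"}
    if not need <= set(records.columns):
        raise ValueError(f"records must carry columns {sorted(need)}")
    rows = []
    for (method, diam), grp in records.groupby(["method", "true_diameter"]):
        vals = grp["predicted_diameter"].to_numpy(dtype=float)
        if vals.size < min_per_cell:
            rows.append({"method": method, "diameter": diam, "mean": np.nan,
                         "median": np.nan, "sd": np.nan, "cv_percent": np.nan,
                         "n": vals.size, "flagged": True})
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        rows.append({
            "method": method, "diameter": float(diam), "mean": mean,
            "median": float(np.median(vals)), "sd": sd,
            "cv_percent": 100.0 * sd / mean if mean != 0 else np.nan,
            "n": int(vals.size), "flagged": False,
        })
    frame = pd.DataFrame(rows).sort_values(["method", "diameter"],
                                           ignore_index=True)
    overall = {
        m: float(g.loc[~g["flagged"], "cv_percent"].mean())
        for m, g in frame.groupby("method")
    }
    return SummaryTable(frame=frame, overall_cv_percent=overall,
                        n_invalid={}, pooled=True)


def _average_repeat_summaries(per_repeat: list[pd.DataFrame]) -> pd.DataFrame:
    allr = pd.concat(per_repeat, ignore_index=True)
    out = (allr[~allr["flagged"]]
           .groupby(["method", "diameter"], as_index=False)
           [["mean", "median", "sd", "cv_percent"]]
           .mean())
    counts = (allr[~allr["flagged"]]
              .groupby(["method", "diameter"], as_index=False)["n"].sum())
    out = out.merge(counts, on=["method", "diameter"])
    out["flagged"] = False
    return out.sort_values(["method", "diameter"], ignore_index=True)


def run_evaluation(dataset: CalibrationDataset,
                   n_repeats: int = 30,
                   test_fraction: float = 0.2,
                   methods: tuple[str, ...] = METHODS,
                   rng: np.random.Generator | int | None = None,
                   pool: bool = False,
                   n_cycles: int = 500,
                   probe_points: int = 200,
                   analytic_source: str = "data",
                   ) -> SummaryTable:
    """Repeated 80/20 evaluation of the three calibration modes.

    Per repeat: the tree ensembles for ``beta0`` and ``beta1`` are trained
    on the training rows (hyperparameters tuned once up front, 500 learning
    cycles), the analytic two-exponential surfaces are fitted, and every
    held-out ``K_norm`` converts to a diameter.  With
    ``analytic_source="data"`` (default) the surfaces are fitted to the
    training rows directly, which makes the analytic mode exact on
    noise-free data; ``analytic_source="model"`` instead probes the trained
    ensemble on the central-band grid and fits the surface to its responses
    (the overfitting-smoothing reading).  Held-out rows whose predicted
    slope is not positive are excluded and counted.  Summaries are computed
    per repeat and averaged; ``pool=True`` pools all predictions before
    summarising instead.
    """
    if analytic_source not in ("data", "model"):
        raise ValueError("analytic_source must be 'data' or 'model'")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if len(dataset) < 10:
        raise ValueError("need >= 10 property sets")
    gen = np.random.default_rng(rng)
    x1, x2 = dataset.surface_inputs()
    X = np.column_stack([x1, x2])
    beta0 = dataset.frame["beta0_true"].to_numpy()
    beta1 = dataset.frame["beta1_true"].to_numpy()
    knorm = dataset.knorm_matrix()
    diam = np.asarray(dataset.diameters_um)
    n = len(dataset)
    n_test = max(1, int(round(test_fraction * n)))

    need_models = ("rf" in methods
                   or ("analytic" in methods and analytic_source == "model"))
    params = {}
    if need_models:
        for name, y in (("beta0", beta0), ("beta1", beta1)):
            tuned = tune_and_train(X, y, rng=gen, n_cycles=n_cycles)
            params[name] = (tuned.method, tuned.learning_rate, tuned.min_leaf)

    beta0_fix, beta1_fix = dataset.ideal_betas()
    n_invalid = {m: 0 for m in methods}
    per_repeat: list[pd.DataFrame] = []
    pooled_records: list[pd.DataFrame] = []

    for _ in range(n_repeats):
        perm = gen.permutation(n)
        test_idx = perm[:n_test]
        train_idx = perm[n_test:]
        preds: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        models = {}
        if need_models:
            for name, y in (("beta0", beta0), ("beta1", beta1)):
                method, lr, leaf = params[name]
                est = _make_estimator(method, lr, leaf, n_cycles=n_cycles,
                                      seed=int(gen.integers(2**31 - 1)))
                est.fit(X[train_idx], y[train_idx])
                models[name] = est
        if "rf" in methods:
            preds["rf"] = (models["beta0"].predict(X[test_idx]),
                           models["beta1"].predict(X[test_idx]))
        if "analytic" in methods:
            surfs = {}
            for name, y in (("beta0", beta0), ("beta1", beta1)):
                if analytic_source == "model":
                    px1, px2, pz = probe_model_surface(
                        models[name], x1[train_idx], x2[train_idx],
                        n_points=probe_points,
                    )
                else:
                    px1, px2, pz = x1[train_idx], x2[train_idx], y[train_idx]
                surfs[name] = fit_analytic_surface(px1, px2, pz,
                                                   response=name)
            preds["analytic"] = (
                np.asarray(surfs["beta0"](x1[test_idx], x2[test_idx])),
                np.asarray(surfs["beta1"](x1[test_idx], x2[test_idx])),
            )
        if "fixed" in methods:
            preds["fixed"] = (np.full(n_test, beta0_fix),
                              np.full(n_test, beta1_fix))

        recs = []
        for method in methods:
            b0_hat, b1_hat = preds[method]
            valid = b1_hat > BETA1_TOLERANCE
            n_invalid[method] += int(np.count_nonzero(~valid))
            for j, row in enumerate(test_idx):
                if not valid[j]:
                    continue
                d_hat = (knorm[row] - b0_hat[j]) / b1_hat[j]
                for d_true, d_pred in zip(diam, d_hat):
                    recs.append({"method": method,
                                 "set_id": int(dataset.frame["set_id"].iloc[row]),
                                 "true_diameter": float(d_true),
                                 "predicted_diameter": float(d_pred)})
        rec_df = pd.DataFrame(recs)
        pooled_records.append(rec_df)
        per_repeat.append(summarize(rec_df).frame)

    if pool:
        table = summarize(pd.concat(pooled_records, ignore_index=True))
        table.n_invalid = n_invalid
        table.pooled = True
        return table
    frame = _average_repeat_summaries(per_repeat)
    overall = {
        m: float(g.loc[~g["flagged"], "cv_percent"].mean())
        for m, g in frame.groupby("method")
    }
    return SummaryTable(frame=frame, overall_cv_percent=overall,
                        n_invalid=n_invalid, pooled=False)
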