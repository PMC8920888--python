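"""OLS land-use-regression fitting and accuracy metrics.

The LUR is an ordinary linear least-squares model of Lden on the engineered
predictors, with classical (non-robust) coefficient standard errors, t values
and two-sided p values.  Predictions are never clipped — extrapolation beyond
the training Lden range is intentional when the model is deployed area-wide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

logger = logging.getLogger(__name__)


@dataclass
class MetricsRecord:
    """R2, adjusted R2 (both unitless) and RMSE/MAE in dB(A)."""

    r2: float
    adj_r2: float
    rmse: float
    mae: float

    def as_dict(self) -> dict:
        return {"r2": self.r2, "adj_r2": self.adj_r2,
                "rmse": self.rmse, "mae": self.mae}


def model_metrics(observed, predicted, p: int) -> MetricsRecord:
    """R2 = 1 - SSres/SStot, adj R2, RMSE = sqrt(SSres/n), MAE.

    ``p`` is the number of predictors (without intercept) used for the
    adjusted R2.  A zero-variance ``observed`` makes R2 undefined (NaN).
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    n = observed.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    resid = observed - predicted
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        r2 = adj_r2 = np.nan
        logger.info("zero-variance response: R2 undefined")
    else:
        r2 = 1.0 - ss_res / ss_tot
        adj_r2 = (1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
                  if n - p - 1 > 0 else np.nan)
    return MetricsRecord(r2=r2, adj_r2=adj_r2,
                         rmse=float(np.sqrt(ss_res / n)),
                         mae=float(np.mean(np.abs(resid))))


@dataclass
class FittedLUR:
    """An OLS fit: coefficient table plus in-sample accuracy metrics.

    ``params[0]`` is the intercept; ``feature_names`` excludes it.
    ``dropped`` lists zero-variance columns removed before fitting.
    """

    feature_names: list[str]
    params: np.ndarray
    std_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    n: int
    metrics: MetricsRecord
    dropped: list[str] = field(default_factory=list)

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def betas(self) -> np.ndarray:
        return self.params[1:]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Linear prediction for a (n, len(feature_names)) design matrix."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(f"design has {X.shape[1]} columns, model expects "
                             f"{len(self.feature_names)}")
        return self.params[0] + X @ self.params[1:]

    def to_json(self, path) -> None:
        import json
        payload = {
            "feature_names": self.feature_names,
            "coefficients": self.coefficient_table(),
            "n": self.n,
            "metrics": self.metrics.as_dict(),
            "dropped": self.dropped,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)

    @classmethod
    def from_json(cls, path) -> "FittedLUR":
        import json
        with open(path) as fh:
            payload = json.load(fh)
        names = payload["feature_names"]
        tab = payload["coefficients"]
        order = ["intercept"] + names
        return cls(
            feature_names=names,
            params=np.array([tab[k]["beta"] for k in order]),
            std_errors=np.array([tab[k]["std_error"] for k in order]),
            t_values=np.array([tab[k]["t_value"] for k in order]),
            p_values=np.array([tab[k]["p_value"] for k in order]),
            n=payload["n"],
            metrics=MetricsRecord(**payload["metrics"]),
            dropped=payload.get("dropped", []),
        )

    def coefficient_table(self) -> dict:
        names = ["intercept"] + self.feature_names
        return {
            name: {"beta": float(b), "std_error": float(se),
                   "t_value": float(t), "p_value": float(p)}
            for name, b, se, t, p in zip(names, self.params, self.std_errors,
                                         self.t_values, self.p_values)
        }


def fit_ols(X: np.ndarray, y: np.ndarray, feature_names=None,
            drop_degenerate: bool = True,
            drop_collinear: bool = False) -> FittedLUR:
    """Fit Lden ~ intercept + X with classical OLS inference.

    Zero-variance columns are dropped with a warning (their coefficients are
    reported as 0 with NaN inference so prediction interfaces stay aligned);
    a rank-deficient design after dropping raises, naming the collinear
    columns — unless ``drop_collinear`` is set, in which case the offending
    columns are dropped like degenerate ones (small-sample campaigns can
    produce exactly collinear designs, e.g. land-cover fractions that sum to
    100 when every class selects the same radius).  Requires ``n > p + 1``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(p)]
    feature_names = list(feature_names)
    if len(feature_names) != p:
        raise ValueError("feature_names length must match design width")
    if y.size != n:
        raise ValueError("y length must match design rows")

    keep = np.ptp(X, axis=0) > 0
    dropped = [nm for nm, k in zip(feature_names, keep) if not k]
    if dropped and not drop_degenerate:
        raise ValueError(f"zero-variance columns: {dropped}")
    if dropped:
        logger.warning("dropping %d zero-variance columns: %s",
                       len(dropped), dropped)
    Xk = X[:, keep]
    pk = Xk.shape[1]
    if n <= pk + 1:
        raise ValueError(f"n = {n} samples cannot identify {pk} predictors "
                         "plus an intercept")
    design = sm.add_constant(Xk, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        kept_names = [nm for nm, k in zip(feature_names, keep) if k]
        collinear = _collinear_columns(design, ["intercept"] + kept_names)
        if not drop_collinear:
            raise ValueError(
                f"rank-deficient design; collinear columns: {collinear}")
        victims = [c for c in collinear if c != "intercept"]
        if not victims:  # pathological: fall back to the last columns
            victims = kept_names[rank - 1:]
        logger.warning("dropping %d collinear columns: %s",
                       len(victims), victims)
        dropped += victims
        keep &= np.array([nm not in victims for nm in feature_names])
        Xk = X[:, keep]
        design = sm.add_constant(Xk, has_constant="add")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("design still rank-deficient after dropping "
                             f"{victims}")
        pk = Xk.shape[1]
    res = sm.OLS(y, design).fit()

    params = np.zeros(p + 1)
    se = np.full(p + 1, np.nan)
    tv = np.full(p + 1, np.nan)
    pv = np.full(p + 1, np.nan)
    full_idx = np.concatenate([[0], 1 + np.nonzero(keep)[0]])
    params[full_idx] = res.params
    se[full_idx] = res.bse
    tv[full_idx] = res.tvalues
    pv[full_idx] = res.pvalues

    metrics = model_metrics(y, res.fittedvalues, p=pk)
    return FittedLUR(feature_names=feature_names, params=params,
                     std_errors=se, t_values=tv, p_values=pv, n=n,
                     metrics=metrics, dropped=dropped)


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    """Name columns whose removal restores full rank (pivoted-QR heuristic)."""
    from scipy.linalg import qr
    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    bad = piv[diag < tol] if diag.size else []
    return [names[i] for i in np.sort(bad)]
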