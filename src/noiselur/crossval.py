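"""Conventional and spatially blocked cross-validation of the LUR.

Four families are implemented:

``loocv``
    leave-one-out; computed exactly through the OLS hat-matrix identity
    ``y_hat(-i) = y_i - e_i / (1 - h_ii)`` (algebraically identical to
    refitting n times) and summarized over the pooled out-of-fold
    predictions;
``lgocv``
    repeated leave-group-out: a random fraction is held out, the model is
    refitted on the rest, metrics evaluated on the held-out group, repeated
    ``repeats`` times and summarized into mean and sd;
``lsocv_admin`` / ``lsocv_landuse``
    leave-structure-out: samples are blocked by the zone containing them
    (administrative district or settlement-structure class) and each block
    is held out once — the harsher, spatially independent test.

Folds whose training set cannot identify the model (``n_train <= p + 1``)
are skipped with a logged reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import FittedLUR, MetricsRecord, fit_ols, model_metrics
from .sampling import SampleSet

logger = logging.getLogger(__name__)

CV_METHODS = ("loocv", "lgocv", "lsocv_admin", "lsocv_landuse")


@dataclass
class CVResult:
    method: str
    param: float | None
    fold_metrics: list[MetricsRecord]
    pooled_predictions: np.ndarray | None  # out-of-fold, aligned to samples
    summary: dict                          # metric -> {"mean":..., "sd":...}
    skipped_folds: int = 0

    def mean(self, metric: str) -> float:
        return self.summary[metric]["mean"]


def _lstsq_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef


def _predict(coef: np.ndarray, X: np.ndarray) -> np.ndarray:
    return coef[0] + X @ coef[1:]


def _summarize(per_fold: list[MetricsRecord]) -> dict:
    out = {}
    for m in ("r2", "adj_r2", "rmse", "mae"):
        vals = np.array([getattr(f, m) for f in per_fold], dtype=float)
        vals = vals[np.isfinite(vals)]
        out[m] = {
            "mean": float(vals.mean()) if vals.size else np.nan,
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
        }
    return out


def run_cv(samples: SampleSet, X: np.ndarray, method: str,
           fraction: float | None = None, repeats: int = 20,
           zone_labels: np.ndarray | None = None, seed: int = 0) -> CVResult:
    """Cross-validate an OLS LUR on a sample design matrix.

    Parameters
    ----------
    samples
        The virtual-microphone draw (supplies ``lden`` and alignment).
    X
        Design matrix (n, p) at the sample cells, column order fixed.
    method
        One of ``loocv``, ``lgocv``, ``lsocv_admin``, ``lsocv_landuse``.
    fraction
        Held-out fraction in (0, 1); required for ``lgocv``.
    repeats
        Number of random held-out groups for ``lgocv``.
    zone_labels
        Per-sample zone label; required for the two ``lsocv`` methods.
    seed
        Drives the ``lgocv`` partitions only.
    """
    if method not in CV_METHODS:
        raise ValueError(f"unknown CV method {method!r}")
    y = samples.lden
    X = np.asarray(X, dtype=float)
    n, p = X.shape

    if method == "loocv":
        return _loocv(y, X)
    if method == "lgocv":
        if fraction is None or not (0.0 < fraction < 1.0):
            raise ValueError("lgocv needs a held-out fraction in (0, 1)")
        return _lgocv(y, X, fraction, repeats, seed)
    if zone_labels is None:
        raise ValueError(f"{method} requires per-sample zone labels")
    return _lsocv(y, X, np.asarray(zone_labels), method)


def _loocv(y: np.ndarray, X: np.ndarray) -> CVResult:
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("too few samples for LOOCV")
    design = np.column_stack([np.ones(n), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    # hat diagonal via the economy QR of the design
    q, _ = np.linalg.qr(design)
    h = np.sum(q * q, axis=1)
    denom = 1.0 - h
    if np.any(denom <= 1e-12):
        raise ValueError("leverage of 1 encountered; LOOCV undefined for "
                         "that sample")
    preds = y - resid / denom
    pooled = model_metrics(y, preds, p=p)
    return CVResult(method="loocv", param=None, fold_metrics=[pooled],
                    pooled_predictions=preds,
                    summary={m: {"mean": getattr(pooled, m), "sd": np.nan}
                             for m in ("r2", "adj_r2", "rmse", "mae")})


def _lgocv(y, X, fraction, repeats, seed) -> CVResult:
    n, p = X.shape
    n_out = max(1, int(round(fraction * n)))
    rng = np.random.default_rng(seed)
    per_fold, skipped = [], 0
    for _ in range(repeats):
        out = rng.choice(n, size=n_out, replace=False)
        train = np.setdiff1d(np.arange(n), out)
        if train.size <= p + 1:
            skipped += 1
            logger.info("lgocv fold skipped: %d training samples cannot "
                        "identify %d predictors", train.size, p)
            continue
        coef = _lstsq_fit(X[train], y[train])
        per_fold.append(model_metrics(y[out], _predict(coef, X[out]), p=p))
    if not per_fold:
        raise ValueError("all lgocv folds were skipped")
    return CVResult(method="lgocv", param=fraction, fold_metrics=per_fold,
                    pooled_predictions=None, summary=_summarize(per_fold),
                    skipped_folds=skipped)


def _lsocv(y, X, labels, method) -> CVResult:
    n, p = X.shape
    per_fold, skipped = [], 0
    preds = np.full(n, np.nan)
    for zone in np.unique(labels):
        out = np.nonzero(labels == zone)[0]
        train = np.nonzero(labels != zone)[0]
        if train.size <= p + 1:
            skipped += 1
            logger.info("%s fold %r skipped: %d training samples", method,
                        zone, train.size)
            continue
        coef = _lstsq_fit(X[train], y[train])
        preds[out] = _predict(coef, X[out])
        if out.size >= 2:
            per_fold.append(model_metrics(y[out], preds[out], p=p))
    if not per_fold and not np.any(np.isfinite(preds)):
        raise ValueError(f"all {method} folds were skipped")
    summary = _summarize(per_fold)
    ok = np.isfinite(preds)
    if ok.sum() >= 2:
        pooled = model_metrics(y[ok], preds[ok], p=p)
        summary["pooled_r2"] = {"mean": pooled.r2, "sd": np.nan}
    return CVResult(method=method, param=None, fold_metrics=per_fold,
                    pooled_predictions=preds, summary=summary,
                    skipped_folds=skipped)


def robustness_check(overall_r2: float, cv_r2: float,
                     threshold: float = 0.15) -> bool:
    """Internal-validity rule: robust iff overall R2 - CV R2 < 0.15 (strict)."""
    return bool(overall_r2 - cv_r2 < threshold)
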