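"""The virtual-field-campaign experiment grid.

One *campaign* is a single (scheme, N, seed) triple: draw the sample, test
its representativity against the mapped population, fit the overall OLS
model, and cross-validate it with every requested method.  The full grid of
the reference design — 4 schemes x 5 sizes (50, 100, 200, 500, 1000) x 100
seeds — yields 2000 independent campaigns; reduced grids follow the same
contract.  Campaigns are independent by construction, so execution order
never affects results.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crossval import run_cv
from .features import FeatureStack
from .geodata import RasterGrid
from .model import fit_ols
from .sampling import SCHEMES, SampleSet, draw_sample, representativity_test

logger = logging.getLogger(__name__)

#: Reference experiment grid of the study design.
DEFAULT_SIZES = (50, 100, 200, 500, 1000)
DEFAULT_N_SEEDS = 100


def campaign_grid(schemes=SCHEMES, sizes=DEFAULT_SIZES,
                  seeds=None) -> list[tuple[str, int, int]]:
    """Enumerate the full (scheme, N, seed) experiment grid.

    Seeds default to the integers 1..100; the reference design enumerates
    4 x 5 x 100 = 2000 campaigns.
    """
    if seeds is None:
        seeds = range(1, DEFAULT_N_SEEDS + 1)
    return list(itertools.product(schemes, sizes, seeds))


def run_campaign(lden: RasterGrid, stack: FeatureStack, scheme: str, N: int,
                 seed: int, cv_methods=(), strata: dict | None = None,
                 zones: dict | None = None, lgocv_repeats: int = 20) -> dict:
    """Execute one campaign and return its flat record.

    ``strata`` maps scheme -> strata raster (for the stratified schemes);
    ``zones`` maps {"admin", "landuse"} -> zone-label raster for the LSOCVs.
    A failed fit is recorded with ``failed = True`` rather than dropped.
    """
    strata = strata or {}
    zones = zones or {}
    rec: dict = {"scheme": scheme, "N_requested": N, "seed": seed,
                 "failed": False}
    sample = draw_sample(lden, scheme, N, seed, strata=strata.get(scheme))
    rec["N_sampled"] = sample.N_sampled
    m, sd, p = representativity_test(sample, lden)
    rec.update(sample_mean=m, sample_sd=sd, t_test_p=p)
    X = stack.matrix(sample.rows, sample.cols)
    try:
        fit = fit_ols(X, sample.lden, feature_names=stack.names,
                      drop_collinear=True)
    except ValueError as err:
        logger.warning("campaign (%s, %d, %d) fit failed: %s",
                       scheme, N, seed, err)
        rec["failed"] = True
        return rec
    rec.update(r2=fit.metrics.r2, adj_r2=fit.metrics.adj_r2,
               rmse=fit.metrics.rmse, mae=fit.metrics.mae)
    # columns dropped from the fit (constant in this draw or exactly
    # collinear) are dropped from the CV design as well
    keep = np.array([nm not in fit.dropped for nm in stack.names])
    X = X[:, keep]
    for method in cv_methods:
        name, kwargs = _cv_spec(method, zones, sample, lgocv_repeats, seed)
        try:
            cv = run_cv(sample, X, name, **kwargs)
        except ValueError as err:
            logger.warning("campaign (%s, %d, %d) %s failed: %s",
                           scheme, N, seed, method, err)
            for metric in ("r2", "rmse", "mae"):
                rec[f"{method}_{metric}"] = np.nan
            continue
        for metric in ("r2", "rmse", "mae"):
            rec[f"{method}_{metric}"] = cv.mean(metric)
    return rec


def _cv_spec(method: str, zones: dict, sample: SampleSet,
             repeats: int, seed: int):
    """Translate a campaign CV name like 'lgocv_25' into run_cv arguments."""
    if method == "loocv":
        return "loocv", {}
    if method.startswith("lgocv"):
        frac = float(method.split("_")[1]) / 100.0
        return "lgocv", {"fraction": frac, "repeats": repeats, "seed": seed}
    if method in ("lsocv_admin", "lsocv_landuse"):
        kind = method.split("_")[1]
        zr = zones.get(kind)
        if zr is None:
            raise ValueError(f"{method} requires a {kind!r} zone raster")
        labels = zr.values[sample.rows, sample.cols]
        return method, {"zone_labels": labels}
    raise ValueError(f"unknown CV method {method!r}")


def run_campaign_grid(lden: RasterGrid, stack: FeatureStack, schemes, sizes,
                      seeds, cv_methods=(), strata: dict | None = None,
                      zones: dict | None = None,
                      lgocv_repeats: int = 20) -> pd.DataFrame:
    """One record per (scheme, N, seed) triple, computed independently."""
    grid = campaign_grid(schemes, sizes, seeds)
    if not grid:
        raise ValueError("empty campaign grid")
    records = [run_campaign(lden, stack, s, n, sd, cv_methods=cv_methods,
                            strata=strata, zones=zones,
                            lgocv_repeats=lgocv_repeats)
               for s, n, sd in grid]
    return pd.DataFrame.from_records(records)


def aggregate_results(table: pd.DataFrame) -> pd.DataFrame:
    """Mean, sd, 5th and 95th percentile of r2/rmse/mae per scheme x size.

    Percentiles use linear interpolation between order statistics; a
    single-record group reports sd as missing.
    """
    metrics = [c for c in ("r2", "adj_r2", "rmse", "mae") if c in table]
    if not metrics:
        raise ValueError("table has no accuracy metric columns")
    rows = []
    for (scheme, n), grp in table.groupby(["scheme", "N_requested"]):
        row = {"scheme": scheme, "N_requested": n, "n_records": len(grp)}
        for m in metrics:
            vals = grp[m].dropna().to_numpy()
            row[f"{m}_mean"] = vals.mean() if vals.size else np.nan
            row[f"{m}_sd"] = vals.std(ddof=1) if vals.size > 1 else np.nan
            if vals.size:
                row[f"{m}_q5"] = np.percentile(vals, 5, method="linear")
                row[f"{m}_q95"] = np.percentile(vals, 95, method="linear")
            else:
                row[f"{m}_q5"] = row[f"{m}_q95"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
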