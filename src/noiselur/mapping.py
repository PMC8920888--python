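"""Deployment of a fitted LUR: area-wide prediction, residual and threshold
reporting.

The prediction is the plain linear model evaluated per cell, unclipped
(extrapolation beyond the training range is expected when a model trained in
one city is deployed to its surroundings).  Residuals are summarized per
5-dB reference bin and intersected with the built-up mask (building height
> 0), where exposure matters most; the threshold report gives the fraction
of the area — overall and built-up — below a planning threshold (default
55 dB(A)) and exports the threshold iso-contour.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure

from .features import FeatureStack
from .geodata import RasterGrid
from .model import FittedLUR


@dataclass
class PredictionReport:
    residual_stats_by_bin: pd.DataFrame | None = None
    mae_overall: float = np.nan
    mae_builtup: float = np.nan
    share_within_2p5: float = np.nan
    area_below_threshold: float = np.nan
    builtup_below_threshold: float = np.nan
    threshold: float = np.nan

    def to_json(self, path: str | Path) -> None:
        payload = {k: v for k, v in self.__dict__.items()
                   if k != "residual_stats_by_bin"}
        if self.residual_stats_by_bin is not None:
            payload["residual_stats_by_bin"] = \
                self.residual_stats_by_bin.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


def predict_raster(model: FittedLUR, stack: FeatureStack) -> RasterGrid:
    """Per-cell linear prediction; nodata propagated, no clipping.

    The stack's column names must match the model's feature names exactly and
    in order — a mismatch raises, listing the difference.
    """
    if stack.names != model.feature_names:
        missing = [n for n in model.feature_names if n not in stack.names]
        extra = [n for n in stack.names if n not in model.feature_names]
        raise ValueError(
            "feature stack does not match the model: "
            f"missing {missing}, unexpected {extra}, "
            f"order {'differs' if not missing and not extra else 'n/a'}")
    grid = stack.grid
    out = np.full(grid.shape, grid.nodata)
    rr, cc = np.nonzero(stack.mask)
    out[rr, cc] = model.predict(stack.matrix(rr, cc))
    return grid.like(out, units="dB(A)")


def residual_analysis(predicted: RasterGrid, reference: RasterGrid,
                      builtup_mask: RasterGrid,
                      bin_width: float = 5.0,
                      tolerance: float = 2.5) -> PredictionReport:
    """Residual (= predicted - reference) summary.

    Per 5-dB reference bin: count, median and IQR of the residual; MAE over
    all valid cells and within the built-up mask; share of built-up cells
    with |residual| <= ``tolerance``.  An empty built-up mask leaves the
    built-up fields missing.
    """
    if not predicted.same_geometry(reference):
        raise ValueError("predicted and reference grids are not aligned")
    valid = predicted.valid_mask & reference.valid_mask
    resid = predicted.values - reference.values
    ref = reference.values

    bins = np.floor(ref[valid] / bin_width).astype(int)
    rows = []
    for b in np.unique(bins):
        r = resid[valid][bins == b]
        rows.append({
            "bin_low": b * bin_width, "bin_high": (b + 1) * bin_width,
            "count": int(r.size), "median": float(np.median(r)),
            "iqr": float(np.percentile(r, 75) - np.percentile(r, 25)),
        })
    report = PredictionReport(
        residual_stats_by_bin=pd.DataFrame(rows),
        mae_overall=float(np.mean(np.abs(resid[valid]))),
    )
    built = builtup_mask.values > 0
    bu = valid & built
    if bu.any():
        report.mae_builtup = float(np.mean(np.abs(resid[bu])))
        report.share_within_2p5 = float(np.mean(np.abs(resid[bu]) <= tolerance))
    return report


def threshold_report(predicted: RasterGrid, builtup_mask: RasterGrid,
                     threshold: float = 55.0):
    """Fractions of valid cells strictly below ``threshold`` plus contours.

    Returns ``(report, contours)``; contours are the marching-squares
    iso-lines of the threshold level in map coordinates (lists of (x, y)
    arrays, following skimage's counter-clockwise-around-high-values
    orientation).
    """
    valid = predicted.valid_mask
    below = predicted.values < threshold
    report = PredictionReport(threshold=float(threshold))
    report.area_below_threshold = float(below[valid].mean()) if valid.any() else np.nan
    built = (builtup_mask.values > 0) & valid
    if built.any():
        report.builtup_below_threshold = float(below[built].mean())
    vals = np.where(valid, predicted.values, np.nan)
    contours = []
    for c in measure.find_contours(vals, threshold):
        x = predicted.origin_x + (c[:, 1] + 0.5) * predicted.cell_size
        y = predicted.origin_y - (c[:, 0] + 0.5) * predicted.cell_size
        contours.append(np.column_stack([x, y]))
    return report, contours


def contours_to_geojson(contours, path: str | Path) -> None:
    feats = [{
        "type": "Feature",
        "geometry": {"type": "LineString",
                     "coordinates": np.asarray(c).tolist()},
        "properties": {"kind": "threshold_contour"},
    } for c in contours]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
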