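"""A-priori moving-window radius selection.

For each windowed variable the single most relevant radius is chosen by the
smallest in-sample RMSE of a bivariate (intercept + slope) linear model of
the sampled Lden on the variable — a deliberately simple univariate screen,
run once and reused by all campaigns.  Ties break toward the smallest
radius; zero-variance columns are skipped with a warning.  Together with the
six proximity features, the reduced stack has 6 + 15 = 21 columns when every
variable survives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureStack
from .sampling import SampleSet

logger = logging.getLogger(__name__)


@dataclass
class RadiusChoice:
    variable: str
    chosen_radius: float
    rmse_by_radius: dict
    r2_by_radius: dict

    def __post_init__(self):
        if self.rmse_by_radius:
            best = min(self.rmse_by_radius.values())
            if not np.isclose(self.rmse_by_radius[self.chosen_radius], best):
                raise ValueError("chosen radius must attain the minimum RMSE")


def _bivariate_rmse_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """In-sample RMSE and R2 of y ~ a + b x (least squares)."""
    res = stats.linregress(x, y)
    b, a = res.slope, res.intercept
    resid = y - (a + b * x)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    rmse = float(np.sqrt(ss_res / y.size))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return rmse, r2


def select_radii(candidate_stack: FeatureStack, response: SampleSet
                 ) -> tuple[list[RadiusChoice], FeatureStack]:
    """Screen every windowed variable across its radii and reduce the stack.

    ``response`` supplies both the sample cells and the Lden values.  The
    reduced stack keeps the proximity columns (unscreened, radius-free) in
    their original order followed by one column per windowed variable at its
    chosen radius.
    """
    if response.N_sampled < 10:
        raise ValueError("radius selection needs at least 10 samples")
    y = response.lden
    X_cells = {s.name: candidate_stack.columns[s.name][response.rows,
                                                      response.cols]
               for s in candidate_stack.specs}

    proximity_names = [s.name for s in candidate_stack.specs if s.radius is None]
    windowed: dict[str, list] = {}
    for s in candidate_stack.specs:
        if s.radius is not None:
            windowed.setdefault(s.variable, []).append(s)

    choices: list[RadiusChoice] = []
    selected_names: list[str] = []
    for variable, specs in windowed.items():
        rmse_by, r2_by, name_by = {}, {}, {}
        for s in sorted(specs, key=lambda s: s.radius):
            x = X_cells[s.name]
            if np.ptp(x) == 0:
                logger.warning("zero-variance column %s skipped in radius "
                               "selection", s.name)
                continue
            rmse, r2 = _bivariate_rmse_r2(x, y)
            rmse_by[s.radius] = rmse
            r2_by[s.radius] = r2
            name_by[s.radius] = s.name
        if not rmse_by:
            logger.warning("variable %s degenerate at every radius; dropped",
                           variable)
            continue
        # ties break toward the smallest radius (dict preserves ascending order)
        chosen = min(rmse_by, key=lambda r: (rmse_by[r], r))
        choices.append(RadiusChoice(variable=variable, chosen_radius=chosen,
                                    rmse_by_radius=rmse_by, r2_by_radius=r2_by))
        selected_names.append(name_by[chosen])

    reduced = candidate_stack.select(proximity_names + selected_names)
    return choices, reduced


def choices_table(choices: list[RadiusChoice]) -> pd.DataFrame:
    """Flat table (variable, radius, rmse, r2) of the selected radii."""
    return pd.DataFrame([{
        "variable": c.variable,
        "radius": c.chosen_radius,
        "rmse": c.rmse_by_radius[c.chosen_radius],
        "r2": c.r2_by_radius[c.chosen_radius],
    } for c in choices])
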