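"""Virtual-microphone sampling campaigns.

A *virtual microphone* is a sampled cell of a reference Lden raster treated
as if it were an in-situ measurement.  Four schemes are supported:

``random``
    uniform draw without replacement over all valid cells;
``systematic``
    a square lattice with spacing ``s = sqrt(valid_area / N)`` whose 2-D
    offset in ``[0, s)^2`` is derived deterministically from the seed,
    lattice points snapped to their containing valid cell;
``stratified_lden``
    equal per-stratum quotas over 5-dB(A) Lden bins;
``stratified_landuse``
    equal per-stratum quotas over settlement-structure (land-use) classes.

Stratified quotas are ``floor(N/K)`` per non-empty stratum with the
remainder given to the largest strata; strata smaller than their quota
contribute all their cells, so the realized ``N_sampled`` can fall short of
the requested ``N``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geodata import RasterGrid

logger = logging.getLogger(__name__)

SCHEMES = ("random", "systematic", "stratified_landuse", "stratified_lden")


@dataclass
class SampleSet:
    """One virtual-microphone draw."""

    rows: np.ndarray
    cols: np.ndarray
    lden: np.ndarray
    scheme: str
    N_requested: int
    N_sampled: int
    seed: int
    strata: np.ndarray | None = None  # stratum label per sample, if stratified

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        self.lden = np.asarray(self.lden, dtype=float)
        if not (len(self.rows) == len(self.cols) == len(self.lden)
                == self.N_sampled):
            raise ValueError("inconsistent sample arrays")
        if self.N_sampled > self.N_requested:
            raise ValueError("N_sampled cannot exceed N_requested")
        cells = set(zip(self.rows.tolist(), self.cols.tolist()))
        if len(cells) != self.N_sampled:
            raise ValueError("sample cells must be unique")

    def __len__(self) -> int:
        return self.N_sampled


def lden_strata(lden: RasterGrid, width: float = 5.0) -> RasterGrid:
    """Integer 5-dB(A) bin labels, left-closed right-open, anchored at 0.

    ``bin(v) = floor(v / width)``: 51.0 falls in [50, 55), 55.0 in [55, 60).
    """
    if width <= 0:
        raise ValueError("stratum width must be > 0")
    out = np.where(lden.valid_mask, np.floor(lden.values / width), lden.nodata)
    return lden.like(out, units="stratum")


def lattice_spacing(valid_area_m2: float, n: int) -> float:
    """Systematic-grid spacing: sqrt(area / N) in meters."""
    return float(np.sqrt(valid_area_m2 / n))


def draw_sample(lden: RasterGrid, scheme: str, N: int, seed: int,
                strata: RasterGrid | None = None) -> SampleSet:
    """Draw one sample set; identical arguments reproduce identical draws."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if N < 1:
        raise ValueError("N must be >= 1")
    stratified = scheme.startswith("stratified")
    if stratified and strata is None:
        raise ValueError(f"scheme {scheme} requires a strata raster")
    mask = lden.valid_mask
    rr, cc = np.nonzero(mask)
    n_pop = rr.size
    if N > n_pop:
        raise ValueError(f"N = {N} exceeds the {n_pop}-cell population")
    rng = np.random.default_rng(seed)

    if scheme == "random":
        take = rng.choice(n_pop, size=N, replace=False)
        sr, sc = rr[take], cc[take]
        labels = None
    elif scheme == "systematic":
        sr, sc = _systematic_cells(lden, mask, N, rng)
        labels = None
    else:
        if not strata.same_geometry(lden):
            raise ValueError("strata raster must share the Lden grid geometry")
        lab = strata.values[rr, cc]
        valid_lab = ~np.isclose(lab, strata.nodata)
        sr, sc, labels = _stratified_cells(rr[valid_lab], cc[valid_lab],
                                           lab[valid_lab], N, rng)

    vals = lden.values[sr, sc]
    return SampleSet(rows=sr, cols=sc, lden=vals, scheme=scheme,
                     N_requested=N, N_sampled=len(sr), seed=int(seed),
                     strata=labels)


def _systematic_cells(lden: RasterGrid, mask: np.ndarray, N: int, rng):
    """Square lattice over the valid area, offset drawn from the seed."""
    area = mask.sum() * lden.cell_size ** 2
    s = lattice_spacing(area, N)
    off = rng.uniform(0.0, s, size=2)
    x_min = lden.origin_x
    y_min = lden.origin_y - lden.n_rows * lden.cell_size
    xs = np.arange(x_min + off[0], x_min + lden.n_cols * lden.cell_size, s)
    ys = np.arange(y_min + off[1], lden.origin_y, s)
    gx, gy = np.meshgrid(xs, ys)
    row, col = lden.cell_of(gx.ravel(), gy.ravel())
    ok = (row >= 0) & (row < lden.n_rows) & (col >= 0) & (col < lden.n_cols)
    row, col = row[ok], col[ok]
    ok = mask[row, col]
    row, col = row[ok], col[ok]
    # snapping can merge lattice points into one cell: dedupe
    flat = row * lden.n_cols + col
    _, first = np.unique(flat, return_index=True)
    row, col = row[np.sort(first)], col[np.sort(first)]
    if len(row) > N:  # edge effects can overshoot the target count
        drop = rng.choice(len(row), size=len(row) - N, replace=False)
        keep = np.setdiff1d(np.arange(len(row)), drop)
        row, col = row[keep], col[keep]
    return row, col


def _stratified_cells(rr, cc, lab, N, rng):
    """Equal allocation floor(N/K) per stratum, remainder to the largest."""
    uniq, counts = np.unique(lab, return_counts=True)
    K = len(uniq)
    base = N // K
    alloc = np.full(K, base)
    remainder = N - base * K
    if remainder > 0:
        order = np.argsort(-counts, kind="stable")
        alloc[order[:remainder]] += 1
    out_r, out_c, out_l = [], [], []
    for k, stratum in enumerate(uniq):
        idx = np.nonzero(lab == stratum)[0]
        want = alloc[k]
        if idx.size <= want:
            take = idx  # scarce stratum: take everything
        else:
            take = idx[rng.choice(idx.size, size=want, replace=False)]
        out_r.append(rr[take])
        out_c.append(cc[take])
        out_l.append(np.full(take.size, stratum))
    return (np.concatenate(out_r), np.concatenate(out_c),
            np.concatenate(out_l))


def representativity_test(sample: SampleSet, population: RasterGrid):
    """Pooled-variance two-sided t-test of the sample against the population.

    Returns ``(sample_mean, sample_sd, p_value)``.  The comparison is against
    *all* valid population cells (including the sampled ones).  With zero
    pooled variance the test degenerates: p = 1 if the means agree, else 0.
    """
    if sample.N_sampled < 2:
        raise ValueError("need at least 2 samples for the t-test")
    pop = population.valid_values()
    m, sd = float(sample.lden.mean()), float(sample.lden.std(ddof=1))
    if np.ptp(sample.lden) == 0 and np.ptp(pop) == 0:
        p = 1.0 if np.isclose(m, pop.mean()) else 0.0
        logger.info("degenerate zero-variance t-test, p = %g", p)
    else:
        _, p = stats.ttest_ind(sample.lden, pop, equal_var=True)
    return m, sd, float(p)
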