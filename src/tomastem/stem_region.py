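"""Locating the main-stem region from the plant's breadth profile.

A potted plant seen from the side is wide at the canopy, thin along the
bare main stem, and wide again at the pot: a "fat-thin-fat" silhouette.
Overlaying a uniform grid on the foreground mask and recording, for each
grid row, how many cells separate the plant axis from the farthest valid
cell produces a bimodal breadth histogram whose valley is exactly the band
of image rows where main stems run bare.  Otsu thresholding -- applied a
second time on the weaker half when the canopy and pot masses are
unbalanced -- localizes the valley, and the within-class standard
deviations on either side of the threshold turn it into an interval
[k* - sigma0, k* + sigma1] of grid rows.  Candidate segments outside that
interval (canopy clutter), or segments in the lower region whose rows are
as wide as a pot, are discarded.

Conventions: image row 0 is at the top; grid/histogram index i increases
downward with i = 1 at the first grid row containing a valid cell (the
origin sits on the plant axis just above the plant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .errors import (DegenerateHistogramError, DegenerateWindowError,
                     EmptyPlantError)
from .hough import Segment
from .rgbd import ForegroundMask

DEFAULT_CELL_PX = 8
DEFAULT_MIN_VALID_FRAC = 0.2
DEFAULT_MEDIAN_WINDOW = 5
DEFAULT_BALANCE_RATIO = 1.5
DEFAULT_POT_BREADTH_MAX = 4.0
#: fraction of foreground rows (from the bottom) used to locate the pot band
POT_BAND_FRAC = 0.15


@dataclass
class GridSystem:
    """Uniform square grid over the image with per-cell validity flags."""

    cell_px: int
    axis_col: float            # plant axis, pixel column
    valid: np.ndarray          # bool, (grid_rows, grid_cols), whole image
    row_start: int             # first grid row containing a valid cell
    row_stop: int              # one past the last such row

    @property
    def axis_cell(self) -> int:
        return int(self.axis_col // self.cell_px)

    @property
    def n_rows(self) -> int:
        """Number of histogram rows L."""
        return self.row_stop - self.row_start

    def hist_row(self, row_px: float) -> int:
        """Histogram index (1-based, may fall outside [1, L]) of a pixel row."""
        return int(row_px // self.cell_px) - self.row_start + 1

    def row_width(self, i: int) -> int:
        """Full width, in valid cells, of histogram row i (clamped)."""
        r = min(max(i, 1), self.n_rows) + self.row_start - 1
        return int(self.valid[r].sum())


@dataclass
class BreadthHistogram:
    n: np.ndarray              # per-row breadths, index 0 <-> histogram row 1

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.int64)

    @property
    def L(self) -> int:
        return int(len(self.n))

    @property
    def N(self) -> int:
        return int(self.n.sum())

    @property
    def p(self) -> np.ndarray:
        """Bar proportions p_i = n_i / N (sums to 1)."""
        return self.n / self.N


@dataclass
class OtsuResult:
    k_star: int
    sigma_b2: float
    omega0: float
    omega1: float
    mu0: float
    mu1: float


@dataclass
class StemInterval:
    k_star: int
    sigma0: float
    sigma1: float
    lo: int
    hi: int
    passes: int
    k_first: int               # first-pass threshold (== k_star when passes == 1)


# ---------------------------------------------------------------------------

def build_grid(mask: ForegroundMask | np.ndarray, cell_px: int = DEFAULT_CELL_PX,
               min_valid_frac: float = DEFAULT_MIN_VALID_FRAC) -> GridSystem:
    """Overlay the grid, flag valid cells, and locate the plant axis.

    A cell is valid when at least ``min_valid_frac`` of its pixels are
    foreground.  The plant axis is vertical (the direction of gravity) and
    passes through the centroid column of the foreground pixels in the
    bottom pot band; if that band is empty the whole-mask centroid is used.
    """
    if cell_px < 2:
        raise ValueError("cell_px must be >= 2")
    m = mask.mask if isinstance(mask, ForegroundMask) else np.asarray(mask, bool)
    if not m.any():
        raise EmptyPlantError("foreground mask is empty")

    rows, cols = np.nonzero(m)
    r_lo, r_hi = rows.min(), rows.max()
    band_start = r_hi - max(1, int(round((r_hi - r_lo + 1) * POT_BAND_FRAC))) + 1
    in_band = rows >= band_start
    axis_col = float(cols[in_band].mean()) if in_band.any() else float(cols.mean())

    h, w = m.shape
    gr, gc = math.ceil(h / cell_px), math.ceil(w / cell_px)
    counts = np.zeros((gr, gc), dtype=np.int64)
    np.add.at(counts, (rows // cell_px, cols // cell_px), 1)
    area = cell_px * cell_px
    valid = counts >= min_valid_frac * area

    valid_rows = np.nonzero(valid.any(axis=1))[0]
    if valid_rows.size == 0:
        raise EmptyPlantError("no grid cell reaches the validity threshold")
    return GridSystem(cell_px=cell_px, axis_col=axis_col, valid=valid,
                      row_start=int(valid_rows[0]), row_stop=int(valid_rows[-1]) + 1)


def breadth_histogram(grid: GridSystem) -> BreadthHistogram:
    """Per-row plant breadth in grid units, with zero-row substitution.

    Row breadth is the grid-cell distance from the axis cell to the
    farthest valid cell, floored at 1 so that a row containing only the
    axis cell still counts as one cell wide; 0 is reserved for rows with no
    valid cell, which inherit the nearest non-zero row above (else below).
    """
    ax = grid.axis_cell
    n = np.zeros(grid.n_rows, dtype=np.int64)
    for i in range(grid.n_rows):
        cells = np.nonzero(grid.valid[grid.row_start + i])[0]
        if cells.size:
            n[i] = max(1, int(np.abs(cells - ax).max()))
    # substitution: nearest non-zero above, else below
    last = 0
    for i in range(len(n)):
        if n[i] == 0:
            if last > 0:
                n[i] = last
        else:
            last = n[i]
    for i in range(len(n) - 1, -1, -1):   # leading zeros fall back to below
        if n[i] == 0 and i + 1 < len(n):
            n[i] = n[i + 1]
    return BreadthHistogram(n=n)


def median_smooth(h: BreadthHistogram,
                  window: int = DEFAULT_MEDIAN_WINDOW) -> BreadthHistogram:
    """Running median with replicate-padded edges."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if window >= 2 * h.L:
        raise DegenerateWindowError(
            f"window {window} degenerate for a histogram of {h.L} bars")
    return BreadthHistogram(n=median_filter(h.n, size=window, mode="nearest"))


def _check_nondegenerate(n: np.ndarray) -> None:
    if (n > 0).sum() < 2:
        raise DegenerateHistogramError(
            "histogram mass concentrated in fewer than two bars")


def between_class_variance(h: BreadthHistogram) -> np.ndarray:
    """sigma_B^2(k) for every candidate threshold k = 1..L.

    Entries where one class is empty are 0 (no split).  Together with the
    within-class variance this decomposes the total variance of bar
    positions: sigma_B^2(k) + sigma_W^2(k) = sigma_T^2 for all k.
    """
    n = h.n
    p = n / n.sum()
    L = h.L
    pos = np.arange(1, L + 1, dtype=float)
    w0 = np.cumsum(p)
    m0 = np.cumsum(pos * p)
    mu_t = m0[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(
            (w0 > 0) & (w0 < 1),
            (mu_t * w0 - m0) ** 2 / (w0 * (1.0 - w0)),
            0.0,
        )


def otsu(h: BreadthHistogram) -> OtsuResult:
    """Threshold maximizing the between-class variance of the breadths.

    Positions i = 1..L carry weights p_i = n_i / N.  For each candidate
    threshold k the histogram splits into C0 = {1..k} and C1 = {k+1..L}
    with weights omega0/omega1 and means mu0/mu1; the between-class
    variance is omega0 * omega1 * (mu1 - mu0)^2 and k* is its argmax over
    a full scan, smallest k on ties.
    """
    n = h.n
    _check_nondegenerate(n)
    L = h.L
    p = n / n.sum()
    pos = np.arange(1, L + 1, dtype=float)
    w0 = np.cumsum(p)                      # omega0(k), k = 1..L
    m0 = np.cumsum(pos * p)                # unnormalized first moment of C0
    mu_t = m0[-1]
    sigma_b2 = between_class_variance(h)
    # smallest k on ties; exact ties can differ by float noise between
    # evaluation orders, so compare at 12 significant digits
    m = float(sigma_b2.max())
    k = int(np.flatnonzero(sigma_b2 >= m - 1e-12 * max(m, 1.0))[0]) + 1
    w0k = float(w0[k - 1])
    mu0 = float(m0[k - 1] / w0k)
    mu1 = float((mu_t - m0[k - 1]) / (1.0 - w0k))
    return OtsuResult(k_star=k, sigma_b2=float(sigma_b2[k - 1]),
                      omega0=w0k, omega1=1.0 - w0k, mu0=mu0, mu1=mu1)


def _weighted_std(positions: np.ndarray, weights: np.ndarray) -> float:
    w = weights.sum()
    if w <= 0:
        return 0.0
    mu = (positions * weights).sum() / w
    return float(np.sqrt(((positions - mu) ** 2 * weights).sum() / w))


def valley_interval(h: BreadthHistogram,
                    balance_ratio: float = DEFAULT_BALANCE_RATIO) -> StemInterval:
    """Locate the valley of the bimodal breadth histogram.

    A first Otsu pass splits the histogram at k1.  When the two classes are
    unbalanced (mass ratio > ``balance_ratio``) the threshold is biased
    toward the heavier class, so Otsu is re-applied on the sub-histogram of
    the weaker side and that sub-threshold (re-indexed globally) becomes
    the final k*.  Two passes at most.  sigma0/sigma1 are the within-class
    standard deviations of bar positions weighted by n_i on each side of
    the final k*, and the stem region is [floor(k* - sigma0),
    ceil(k* + sigma1)] clamped to [1, L].
    """
    n = h.n
    first = otsu(h)
    k1 = first.k_star
    mass0, mass1 = float(n[:k1].sum()), float(n[k1:].sum())
    k_star, passes = k1, 1
    if min(mass0, mass1) > 0 and max(mass0, mass1) / min(mass0, mass1) > balance_ratio:
        if mass0 < mass1:
            sub = BreadthHistogram(n=n[:k1])
            try:
                k_star = otsu(sub).k_star
                passes = 2
            except DegenerateHistogramError:
                pass
        else:
            sub = BreadthHistogram(n=n[k1:])
            try:
                k_star = k1 + otsu(sub).k_star
                passes = 2
            except DegenerateHistogramError:
                pass
    pos = np.arange(1, h.L + 1, dtype=float)
    s0 = _weighted_std(pos[:k_star], n[:k_star].astype(float))
    s1 = _weighted_std(pos[k_star:], n[k_star:].astype(float))
    lo = max(1, math.floor(k_star - s0))
    hi = min(h.L, math.ceil(k_star + s1))
    return StemInterval(k_star=k_star, sigma0=s0, sigma1=s1,
                        lo=lo, hi=hi, passes=passes, k_first=k1)


def filter_segments(segs: list[Segment], interval: StemInterval,
                    grid: GridSystem,
                    pot_breadth_max: float = DEFAULT_POT_BREADTH_MAX,
                    ) -> list[Segment]:
    """Remove canopy and pot false positives.

    A segment is kept iff (a) its grid-row span intersects [lo, hi], and
    (b) when its midpoint lies below k* (the lower region), the mean full
    valid-cell width of its spanned rows is <= ``pot_breadth_max`` --
    pot-region cross sections are much wider than a main stem.
    """
    kept = []
    for s in segs:
        r0 = grid.hist_row(s.p0[1])
        r1 = grid.hist_row(s.p1[1])
        if r1 < interval.lo or r0 > interval.hi:
            continue
        mid = grid.hist_row((s.p0[1] + s.p1[1]) / 2.0)
        if mid > interval.k_star:
            widths = [grid.row_width(i) for i in range(r0, r1 + 1)]
            if np.mean(widths) > pot_breadth_max:
                continue
        kept.append(s)
    return kept
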