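"""Performance surfaces over (peak gape, peak jaw protrusion) and their peaks.

A fitted GAM containing the bivariate smooth s(g, jp) is evaluated on a
rectangular grid spanning the observed kinematics, with parametric terms
held at reference levels (generalist species, edge strikes, other linear
covariates at their training means).  Predictions are only meaningful
inside the convex hull of the observed (g, jp) points, so grid cells
outside the hull are masked.

Peaks are hull-interior grid cells strictly greater than all eight
neighbors, filtered by topographic prominence: the drop from the peak to
the highest saddle connecting it to higher ground (computed by
persistence over the unmasked cells), expressed relative to the fitted
surface's range.  This suppresses noise ripples while keeping genuinely
isolated optima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from .errors import ValidationError
from .gam import REFERENCE_LEVELS, FittedGAM


@dataclass
class Peak:
    g: float
    jp: float
    value: float
    prominence: float


@dataclass
class PeakReport:
    count: int
    peaks: list
    prominence_threshold: float


@dataclass
class PerformanceSurface:
    """Gridded GAM prediction over (g, jp) with a convex-hull mask."""

    g_grid: np.ndarray  # shape (nx,)
    jp_grid: np.ndarray  # shape (ny,)
    values: np.ndarray  # shape (nx, ny)
    hull_mask: np.ndarray  # shape (nx, ny) bool, True inside hull
    response: str = ""

    def to_frame(self) -> pd.DataFrame:
        gg, jj = np.meshgrid(self.g_grid, self.jp_grid, indexing="ij")
        return pd.DataFrame(
            {
                "g": gg.ravel(),
                "jp": jj.ravel(),
                "value": self.values.ravel(),
                "inside_hull": self.hull_mask.ravel(),
            }
        )


def predict_surface(
    fit: FittedGAM,
    grid_resolution: int = 50,
    reference_levels: dict | None = None,
) -> PerformanceSurface:
    """Evaluate the fitted (g, jp) surface on a grid with a hull mask."""
    smooth = fit.bivariate_smooth
    if smooth is None:
        raise ValidationError("fit has no bivariate s(g, jp) term")
    gv, jv = smooth.variables
    refs = dict(REFERENCE_LEVELS)
    refs.update(reference_levels or {})
    g_lo, g_hi = fit._train_ranges[gv]
    j_lo, j_hi = fit._train_ranges[jv]
    g_grid = np.linspace(g_lo, g_hi, grid_resolution)
    jp_grid = np.linspace(j_lo, j_hi, grid_resolution)
    gg, jj = np.meshgrid(g_grid, jp_grid, indexing="ij")

    newdata = pd.DataFrame({gv: gg.ravel(), jv: jj.ravel()})
    for f in fit.spec.factors:
        levels = fit._factor_levels[f]
        lev = refs.get(f, levels[0])
        if lev not in levels:
            lev = levels[0]
        newdata[f] = lev
    for v in fit.spec.linear:
        newdata[v] = fit._train_means[v]
    values = fit.predict(newdata).reshape(gg.shape)

    pts = fit._blocks[smooth.label].knots
    try:
        tri = Delaunay(pts)
        inside = tri.find_simplex(np.column_stack([gg.ravel(), jj.ravel()])) >= 0
    except QhullError as exc:
        raise ValidationError(f"observed (g, jp) points are degenerate: {exc}") from exc
    return PerformanceSurface(
        g_grid=g_grid,
        jp_grid=jp_grid,
        values=values,
        hull_mask=inside.reshape(gg.shape),
        response=fit.spec.response,
    )


def _neighbors(i, j, nx, ny):
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            a, b = i + di, j + dj
            if 0 <= a < nx and 0 <= b < ny:
                yield a, b


def _persistence(values: np.ndarray, mask: np.ndarray) -> dict:
    """Topographic prominence of each local peak over the unmasked cells.

    Cells are activated in decreasing value order with union-find; a
    component's birth is its peak value, and when two components merge
    the lower-born peak dies at the merge level.  The globally highest
    peak's prominence is its height above the unmasked minimum.
    """
    nx, ny = values.shape
    cells = [(i, j) for i in range(nx) for j in range(ny) if mask[i, j]]
    cells.sort(key=lambda c: values[c], reverse=True)
    parent = {}
    birth = {}
    peak_of = {}
    prominence = {}

    def find(c):
        root = c
        while parent[root] != root:
            root = parent[root]
        while parent[c] != root:
            parent[c], c = root, parent[c]
        return root

    for c in cells:
        parent[c] = c
        birth[c] = values[c]
        peak_of[c] = c
        for nb in _neighbors(*c, nx, ny):
            if nb in parent:
                ra, rb = find(c), find(nb)
                if ra == rb:
                    continue
                # keep the higher-born component; the other peak dies here
                if birth[ra] < birth[rb]:
                    ra, rb = rb, ra
                prominence[peak_of[rb]] = birth[rb] - values[c]
                parent[rb] = ra
    vmin = min(values[c] for c in cells)
    for c in cells:
        r = find(c)
        if peak_of[r] not in prominence:
            prominence[peak_of[r]] = birth[r] - vmin
    return prominence


def count_interior_peaks(
    surface: PerformanceSurface, prominence_frac: float = 0.05
) -> PeakReport:
    """Count prominent local maxima interior to the observed hull.

    A peak is an unmasked cell, all of whose eight neighbors exist and
    are unmasked (hull interior), strictly greater than each of them,
    with prominence at least ``prominence_frac`` of the unmasked surface
    range.  Invariant to monotone affine transforms of the values.
    """
    vals, mask = surface.values, surface.hull_mask
    nx, ny = vals.shape
    if nx < 20 or ny < 20:
        raise ValidationError("grid must be at least 20 x 20")
    if not mask.any():
        raise ValidationError("surface is fully masked")
    vrange = float(vals[mask].max() - vals[mask].min())
    threshold = prominence_frac * vrange
    if vrange == 0:  # flat surface: no interior maximum
        return PeakReport(count=0, peaks=[], prominence_threshold=threshold)
    prominence = _persistence(vals, mask)

    peaks = []
    # persistence yields one representative cell per local-maximum
    # plateau, so grid-discretization ties are counted exactly once
    for (i, j), prom in prominence.items():
        if prom < threshold:
            continue
        nbs = list(_neighbors(i, j, nx, ny))
        if len(nbs) < 8 or not all(mask[a, b] for a, b in nbs):
            continue
        if not all(vals[i, j] >= vals[a, b] for a, b in nbs):
            continue
        peaks.append(
            Peak(
                g=float(surface.g_grid[i]),
                jp=float(surface.jp_grid[j]),
                value=float(vals[i, j]),
                prominence=float(prom),
            )
        )
    peaks.sort(key=lambda p: p.value, reverse=True)
    return PeakReport(count=len(peaks), peaks=peaks, prominence_threshold=threshold)
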