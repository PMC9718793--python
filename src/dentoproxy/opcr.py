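"""Orientation Patch Count Rotated (OPCR) dental complexity.

The crown surface is resampled onto a square raster standardised to a fixed
number of rows per tooth (RPT) along the mesiodistal axis.  Each cell is
assigned the compass direction of steepest descent, discretised into eight
45° bins; contiguous same-bin cells form patches and patches of at least
``min_patch_size`` cells are counted.  Because the result depends on where
the bin boundaries fall, the binning is repeated at eight rotations of the
boundaries (5.625° apart) and the patch counts averaged — the "rotated"
part of OPCR.  This is the raster (2.5D) formulation; a monotone
single-aspect surface always scores exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .surfaces import CrownMesh, HeightMap

FLAT = -1

_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass
class GridSpec:
    """Raster standardisation: ``rpt`` square rows along the mesiodistal axis."""

    rpt: int = 50
    interpolation: str = "max-z"

    def __post_init__(self):
        if self.rpt < 4:
            raise ValueError("rpt must be at least 4")


@dataclass
class OrientationGrid:
    """Per-cell aspect bin in {0..7}, FLAT (-1), or -2 outside the footprint."""

    bins: np.ndarray
    rotation_offset: float
    footprint: np.ndarray


@dataclass
class OPCRResult:
    per_rotation_counts: list[int]
    opcr: float
    rpt_used: int
    min_patch_size: int
    per_rotation_bin_counts: list[dict[int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------


def align_mesiodistal(mesh: CrownMesh) -> CrownMesh:
    """Rotate the mesh about +Z so the footprint's long (mesiodistal) axis
    lies along +Y.  Helper only; callers may orient meshes themselves."""
    xy = mesh.vertices[:, :2] - mesh.vertices[:, :2].mean(axis=0)
    cov = xy.T @ xy
    w, v = np.linalg.eigh(cov)
    major = v[:, np.argmax(w)]
    ang = np.arctan2(major[1], major[0]) - np.pi / 2
    c, s = np.cos(-ang), np.sin(-ang)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return CrownMesh(mesh.vertices @ R.T, mesh.faces, mesh.apicobasal_axis, mesh.label)


def rasterize_crown(mesh: CrownMesh, spec: GridSpec) -> HeightMap:
    """Resample a crown mesh onto a square grid of ``rpt`` rows.

    Rows run along the mesh's y (mesiodistal) axis; cell spacing is the
    mesiodistal extent divided by ``rpt``.  Each cell records the highest
    surface elevation over its center (a vertical max-z ray), so overhangs
    keep the top surface.  Cells outside the crown footprint are masked.
    """
    v, f = mesh.vertices, mesh.faces
    if f.size == 0:
        raise ValueError("mesh has no faces")
    ymin, ymax = v[:, 1].min(), v[:, 1].max()
    xmin, xmax = v[:, 0].min(), v[:, 0].max()
    if ymax <= ymin or xmax <= xmin:
        raise ValueError("crown footprint is empty")
    h = (ymax - ymin) / spec.rpt
    ncols = max(int(np.ceil((xmax - xmin) / h)), 1)
    # cell centers; row 0 = max y (image convention)
    xc = xmin + (np.arange(ncols) + 0.5) * h
    yc = ymax - (np.arange(spec.rpt) + 0.5) * h

    heights = np.full((spec.rpt, ncols), -np.inf)
    tri = v[f]  # (m, 3, 3)
    for a, b, c in tri:
        i0 = int(np.searchsorted(-yc, -max(a[1], b[1], c[1])))
        i1 = int(np.searchsorted(-yc, -min(a[1], b[1], c[1]), side="right"))
        j0 = int(np.searchsorted(xc, min(a[0], b[0], c[0])))
        j1 = int(np.searchsorted(xc, max(a[0], b[0], c[0]), side="right"))
        if i0 >= i1 or j0 >= j1:
            continue
        X, Y = np.meshgrid(xc[j0:j1], yc[i0:i1])
        d = (b[1] - c[1]) * (a[0] - c[0]) + (c[0] - b[0]) * (a[1] - c[1])
        if abs(d) < 1e-30:
            continue  # vertical triangle: no footprint area
        w1 = ((b[1] - c[1]) * (X - c[0]) + (c[0] - b[0]) * (Y - c[1])) / d
        w2 = ((c[1] - a[1]) * (X - c[0]) + (a[0] - c[0]) * (Y - c[1])) / d
        w3 = 1.0 - w1 - w2
        inside = (w1 >= -1e-12) & (w2 >= -1e-12) & (w3 >= -1e-12)
        if not inside.any():
            continue
        z = w1 * a[2] + w2 * b[2] + w3 * c[2]
        block = heights[i0:i1, j0:j1]
        np.maximum(block, np.where(inside, z, -np.inf), out=block)

    mask = np.isfinite(heights)
    if not mask.any():
        raise ValueError("no grid cell center falls inside the crown footprint")
    heights[~mask] = np.nan
    return HeightMap(heights, dx=h, dy=h, mask=mask, origin=(xc[0], yc[0]), label=mesh.label)


def _masked_gradient(z: np.ndarray, mask: np.ndarray, dx: float, dy: float):
    """Central differences where both neighbors are measured, one-sided at
    footprint edges, zero where no neighbor is available."""
    ny, nx = z.shape
    zp = np.where(mask, z, np.nan)

    def axis_grad(pad_axis, spacing):
        padded = np.pad(zp, 1, constant_values=np.nan)
        if pad_axis == 1:
            lo, hi = padded[1:-1, :-2], padded[1:-1, 2:]
        else:
            lo, hi = padded[:-2, 1:-1], padded[2:, 1:-1]
        ok_lo, ok_hi = np.isfinite(lo), np.isfinite(hi)
        g = np.zeros_like(z)
        both = ok_lo & ok_hi
        g[both] = (hi[both] - lo[both]) / (2 * spacing)
        only_hi = ok_hi & ~ok_lo
        g[only_hi] = (hi[only_hi] - zp[only_hi]) / spacing
        only_lo = ok_lo & ~ok_hi
        g[only_lo] = (zp[only_lo] - lo[only_lo]) / spacing
        return g

    gx = axis_grad(1, dx)
    # row index increases as y decreases, so flip the sign for d/dy
    gy = -axis_grad(0, dy)
    gx[~mask] = 0.0
    gy[~mask] = 0.0
    return gx, gy


def orientation_bins(
    hmap: HeightMap, rotation_offset: float = 0.0, flat_tolerance: float = 0.0
) -> OrientationGrid:
    """Assign each footprint cell a downhill-aspect bin.

    Aspect is the direction of steepest descent from central differences,
    measured counterclockwise from +x in degrees.  Bin k covers the
    half-open interval [rotation_offset + 45k, rotation_offset + 45(k+1));
    a boundary aspect therefore lands in the higher bin.  Cells with slope
    magnitude <= ``flat_tolerance`` are FLAT (default 0: only exactly flat).
    """
    gx, gy = _masked_gradient(hmap.heights, hmap.mask, hmap.dx, hmap.dy)
    slope = np.hypot(gx, gy)
    aspect = np.degrees(np.arctan2(-gy, -gx)) % 360.0
    bins = np.floor(((aspect - rotation_offset) % 360.0) / 45.0).astype(int)
    bins = np.clip(bins, 0, 7)  # guard against 360/45 rounding
    bins[slope <= flat_tolerance] = FLAT
    bins[~hmap.mask] = -2
    return OrientationGrid(bins=bins, rotation_offset=rotation_offset, footprint=hmap.mask.copy())


def count_patches(
    grid: OrientationGrid, min_patch_size: int = 3, connectivity: int = 4
) -> tuple[int, dict[int, int]]:
    """Count connected same-bin patches of at least ``min_patch_size`` cells.

    FLAT and out-of-footprint cells belong to no patch.  Returns the total
    count and a per-bin breakdown.
    """
    structure = _STRUCTURE_4 if connectivity == 4 else _STRUCTURE_8
    per_bin: dict[int, int] = {}
    total = 0
    for b in range(8):
        lab, n = ndimage.label(grid.bins == b, structure=structure)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            count = int((sizes >= min_patch_size).sum())
        else:
            count = 0
        per_bin[b] = count
        total += count
    return total, per_bin


def opcr(
    mesh_or_map: CrownMesh | HeightMap,
    spec: GridSpec | None = None,
    min_patch_size: int = 3,
    n_rotations: int = 8,
    flat_tolerance: float = 0.0,
    connectivity: int = 4,
) -> OPCRResult:
    """Full OPCR: eight 45° aspect bins, patches of >= ``min_patch_size``
    cells, repeated at ``n_rotations`` bin-boundary rotations of
    45°/``n_rotations`` each, averaged."""
    if n_rotations < 1:
        raise ValueError("n_rotations must be >= 1")
    spec = spec or GridSpec()
    if isinstance(mesh_or_map, CrownMesh):
        hmap = rasterize_crown(mesh_or_map, spec)
        rpt_used = spec.rpt
    else:
        hmap = mesh_or_map
        rpt_used = hmap.shape[0]

    counts, bin_counts = [], []
    step = 45.0 / n_rotations
    for k in range(n_rotations):
        grid = orientation_bins(hmap, rotation_offset=k * step, flat_tolerance=flat_tolerance)
        total, per_bin = count_patches(grid, min_patch_size, connectivity)
        counts.append(total)
        bin_counts.append(per_bin)
    return OPCRResult(
        per_rotation_counts=counts,
        opcr=float(np.mean(counts)),
        rpt_used=rpt_used,
        min_patch_size=min_patch_size,
        per_rotation_bin_counts=bin_counts,
    )
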