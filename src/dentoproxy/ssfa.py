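"""Scale-sensitive fractal analysis of wear-surface height maps.

A rough surface has more measurable area the finer the scale at which it is
triangulated; SSFA characterises wear texture by how relative area and
relative profile length change with scale:

* ``Asfc`` (area-scale fractal complexity): -1000 x the steepest slope of
  log(relative area) against log(scale);
* ``Smc`` (scale of maximum complexity): the finest scale of the steepest
  window;
* ``epLsar`` (exact-proportion length-scale anisotropy of relief): the
  directional concentration of transect relative lengths, measured on
  doubled (axial) angles;
* ``HAsfc`` : heterogeneity of Asfc over a 9x9 partition of the region,
  as median absolute deviation / median.

Maps are leveled (least-squares plane) and hole-filled before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import LevelingError
from .surfaces import HeightMap

DEFAULT_EPLSAR_SCALE_UM = 1.8
DEFAULT_ANGLE_STEP_DEG = 5.0
DEFAULT_SLOPE_WINDOW = 5


@dataclass
class SSFAResult:
    asfc: float
    smc: float  # µm²
    eplsar: float
    eplsar_direction: float  # degrees, orientation of maximal relief transects
    texture_direction: float  # degrees, orientation of the texture (ridges/scratches)
    hasfc9: float
    relative_area_curve: list[tuple[float, float]] = field(default_factory=list)
    rose: dict[float, float] = field(default_factory=dict)  # θ -> exact proportion


# ---------------------------------------------------------------------------
# leveling and region extraction
# ---------------------------------------------------------------------------


def level(hmap: HeightMap) -> HeightMap:
    """Subtract the ordinary-least-squares best-fit plane of measured cells."""
    ny, nx = hmap.shape
    ii, jj = np.indices((ny, nx))
    x = jj[hmap.mask] * hmap.dx
    y = ii[hmap.mask] * hmap.dy
    z = hmap.heights[hmap.mask]
    if len(z) < 3:
        raise LevelingError("need at least 3 measured cells to level")
    A = np.column_stack([x, y, np.ones_like(x)])
    coef, _, rank, _ = np.linalg.lstsq(A, z, rcond=None)
    if rank < 3:
        raise LevelingError("measured cells are collinear; plane fit is degenerate")
    out = hmap.copy()
    plane = coef[0] * (jj * hmap.dx) + coef[1] * (ii * hmap.dy) + coef[2]
    out.heights = hmap.heights - plane
    out.heights[~hmap.mask] = np.nan
    return out


def extract_region(hmap: HeightMap, size: int) -> HeightMap:
    """Centered ``size`` x ``size`` crop (offsets floored), spacing preserved."""
    ny, nx = hmap.shape
    if size > ny or size > nx:
        raise ValueError(f"crop size {size} exceeds grid {hmap.shape}")
    i0, j0 = (ny - size) // 2, (nx - size) // 2
    return HeightMap(
        hmap.heights[i0 : i0 + size, j0 : j0 + size].copy(),
        hmap.dx,
        hmap.dy,
        hmap.mask[i0 : i0 + size, j0 : j0 + size].copy(),
        origin=(hmap.origin[0] + j0 * hmap.dx, hmap.origin[1] - i0 * hmap.dy),
        label=hmap.label,
    )


# ---------------------------------------------------------------------------
# area-scale analysis
# ---------------------------------------------------------------------------


def _require_filled(hmap: HeightMap, what: str) -> None:
    if not hmap.fully_measured:
        raise ValueError(f"{what} requires a fully measured (hole-filled) map")


def relative_area(hmap: HeightMap, step: int) -> tuple[float, float]:
    """Relative area at the virtual-triangle scale set by ``step`` cells.

    The grid is decimated to every ``step``-th sample; each square of the
    decimated grid is split into two triangles whose 3-D areas are summed
    and divided by the summed projected areas.  Returns
    ``(scale_um2, ratio)`` where scale is the projected area of one
    triangle, ``step² · dx · dy / 2``.
    """
    _require_filled(hmap, "relative_area")
    ny, nx = hmap.shape
    if step < 1 or step > (min(ny, nx) - 1):
        raise ValueError(f"step {step} out of range for grid {hmap.shape}")
    z = hmap.heights[::step, ::step]
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("decimated grid too small")
    ax, ay = step * hmap.dx, step * hmap.dy
    z00 = z[:-1, :-1]
    z01 = z[:-1, 1:]
    z10 = z[1:, :-1]
    z11 = z[1:, 1:]

    # triangle 1: (00) -> (01) -> (10); triangle 2: (11) -> (10) -> (01)
    # edge vectors in µm: u = (ax, 0, dz), v = (0, ay, dz)
    def area_pair(zc, za, zb):
        u = np.stack([np.full_like(zc, ax), np.zeros_like(zc), za - zc], axis=-1)
        v = np.stack([np.zeros_like(zc), np.full_like(zc, ay), zb - zc], axis=-1)
        return 0.5 * np.linalg.norm(np.cross(u, v), axis=-1)

    a1 = area_pair(z00, z01, z10)
    a2 = area_pair(z11, z10, z01)
    total_3d = float(a1.sum() + a2.sum())
    # summed the same way as the 3-D areas so a flat surface is exactly 1
    p = np.full_like(a1, ax * ay / 2.0)
    proj = float(p.sum() + p.sum())
    scale = ax * ay / 2.0
    return scale, total_3d / proj


def dyadic_steps(n_cells: int, min_step: int = 2) -> list[int]:
    """Step series with ~√2 ratio, so triangle areas roughly double."""
    steps = []
    s = float(min_step)
    while round(s) <= max(n_cells // 2, min_step):
        k = int(round(s))
        if k <= n_cells - 1 and (not steps or k != steps[-1]):
            steps.append(k)
        s *= np.sqrt(2.0)
    return steps


def relative_area_curve(hmap: HeightMap, min_step: int = 2) -> list[tuple[float, float]]:
    """(scale µm², relative area) at a dyadic-in-area series of scales,
    finest first."""
    steps = dyadic_steps(min(hmap.shape) - 1, min_step=min_step)
    return [relative_area(hmap, k) for k in steps]


def asfc_smc(
    curve: list[tuple[float, float]], window: int = DEFAULT_SLOPE_WINDOW
) -> tuple[float, float]:
    """Area-scale fractal complexity and scale of maximum complexity.

    ``curve`` is (scale, relative area), finest scale first.  The slope of
    log(relative area) vs log(scale) is estimated by OLS over every run of
    ``window`` consecutive scales; Asfc is -1000 x the steepest (most
    negative) slope and Smc the finest scale of that window.  Ties go to
    the finer-scale window.
    """
    if len(curve) < window:
        raise ValueError(f"curve has {len(curve)} scales, fewer than window {window}")
    curve = sorted(curve, key=lambda p: p[0])
    ls = np.log([p[0] for p in curve])
    la = np.log([max(p[1], 1.0) for p in curve])
    best_slope, best_start = np.inf, 0
    for start in range(len(curve) - window + 1):
        sl = np.polyfit(ls[start : start + window], la[start : start + window], 1)[0]
        if sl < best_slope - 1e-15:
            best_slope, best_start = sl, start
    asfc = -1000.0 * min(best_slope, 0.0) + 0.0  # + 0.0 normalises -0.0
    return float(asfc), float(curve[best_start][0])


# ---------------------------------------------------------------------------
# anisotropy
# ---------------------------------------------------------------------------


def _transect_relative_lengths(
    hmap: HeightMap, theta_deg: float, length_scale: float, n_transects: int
) -> float:
    """Mean relative length of parallel transects in direction ``theta``.

    Samples heights by bilinear interpolation at ``length_scale`` spacing
    along each transect; relative length = summed 3-D segment length over
    summed projected length."""
    ny, nx = hmap.shape
    W, H = (nx - 1) * hmap.dx, (ny - 1) * hmap.dy
    th = np.radians(theta_deg)
    d = np.array([np.cos(th), np.sin(th)])  # µm-space direction
    p = np.array([-d[1], d[0]])  # perpendicular
    cx, cy = W / 2.0, H / 2.0
    half_diag = 0.5 * np.hypot(W, H)
    offsets = np.linspace(-half_diag, half_diag, n_transects)
    t = np.arange(-half_diag, half_diag + length_scale, length_scale)

    rels = []
    for off in offsets:
        xs = cx + off * p[0] + t * d[0]
        ys = cy + off * p[1] + t * d[1]
        ok = (xs >= 0) & (xs <= W) & (ys >= 0) & (ys <= H)
        if ok.sum() < 4:  # need >= 3 segments
            continue
        xs, ys = xs[ok], ys[ok]
        # map µm -> fractional indices; row 0 = max y
        cols = xs / hmap.dx
        rows = (H - ys) / hmap.dy
        z = ndimage.map_coordinates(hmap.heights, [rows, cols], order=1, mode="nearest")
        dz = np.diff(z)
        seg3d = np.sqrt(length_scale**2 + dz**2)
        rels.append(seg3d.sum() / (length_scale * len(dz)))
    if not rels:
        raise ValueError("no transect long enough for 3 segments; region too small")
    return float(np.mean(rels))


def eplsar(
    hmap: HeightMap,
    length_scale: float = DEFAULT_EPLSAR_SCALE_UM,
    angle_step: float = DEFAULT_ANGLE_STEP_DEG,
    n_transects: int = 36,
) -> tuple[float, float, dict[float, float]]:
    """Exact-proportion length-scale anisotropy of relief.

    For each direction θ in [0°, 180°) the mean transect relative length is
    computed, lengths are normalised to exact proportions summing to 1, and
    the anisotropy is the resultant length of the proportion-weighted mean
    vector on doubled angles (orientations are axial).  Returns
    ``(eplsar, direction_of_max_relief, rose)`` where the rose maps θ to
    its proportion.  The texture (scratch/ridge) orientation is
    perpendicular to the returned direction.
    """
    _require_filled(hmap, "eplsar")
    thetas = np.arange(0.0, 180.0, angle_step)
    lengths = np.array(
        [_transect_relative_lengths(hmap, th, length_scale, n_transects) for th in thetas]
    )
    props = lengths / lengths.sum()
    ang2 = np.radians(2.0 * thetas)
    sx = float(np.sum(props * np.cos(ang2)))
    sy = float(np.sum(props * np.sin(ang2)))
    # a perfectly isotropic rose has proportions 1/n, whose doubled-angle
    # resultant is 0; subtracting the uniform baseline is implicit because
    # the uniform component sums to zero over the evenly spaced angles
    ep = float(np.hypot(sx, sy))
    direction = float(np.degrees(0.5 * np.arctan2(sy, sx)) % 180.0)
    rose = {float(th): float(pr) for th, pr in zip(thetas, props)}
    return ep, direction, rose


def texture_direction(direction_of_max_relief: float) -> float:
    """Ridge/scratch orientation: perpendicular to the max-relief direction."""
    return (direction_of_max_relief + 90.0) % 180.0


# ---------------------------------------------------------------------------
# heterogeneity
# ---------------------------------------------------------------------------


def hasfc(
    hmap: HeightMap,
    grid: tuple[int, int] = (9, 9),
    window: int = DEFAULT_SLOPE_WINDOW,
    min_step: int = 2,
) -> float:
    """Heterogeneity of Asfc over a ``grid`` partition (default 9x9).

    The region is split into equal cells (remainder rows/columns dropped at
    the far edges), Asfc is computed per cell, and heterogeneity is
    median(|Asfc_i - median|) / median.  All-equal cell values (including
    an all-zero plane) give 0.  The per-cell slope window is clamped to the
    number of scales a small cell supports.
    """
    _require_filled(hmap, "hasfc")
    gy, gx = grid
    ny, nx = hmap.shape
    cy, cx = ny // gy, nx // gx
    if cy < 3 or cx < 3:
        raise ValueError(f"cells of {cy}x{cx} cells are too small for a {gy}x{gx} partition")
    values = []
    for i in range(gy):
        for j in range(gx):
            sub = HeightMap(
                hmap.heights[i * cy : (i + 1) * cy, j * cx : (j + 1) * cx].copy(),
                hmap.dx,
                hmap.dy,
            )
            try:
                curve = relative_area_curve(sub, min_step=min_step)
                a, _ = asfc_smc(curve, window=min(window, len(curve)))
            except ValueError as exc:
                raise ValueError(f"hasfc cell ({i}, {j}) is degenerate: {exc}") from exc
            values.append(a)
    values = np.asarray(values)
    med = float(np.median(values))
    if med == 0.0 or np.allclose(values, values[0]):
        return 0.0
    return float(np.median(np.abs(values - med)) / med)


# ---------------------------------------------------------------------------
# one-call driver
# ---------------------------------------------------------------------------


def analyze(
    hmap: HeightMap,
    crop: int | None = None,
    length_scale: float = DEFAULT_EPLSAR_SCALE_UM,
    angle_step: float = DEFAULT_ANGLE_STEP_DEG,
    window: int = DEFAULT_SLOPE_WINDOW,
    hasfc_grid: tuple[int, int] = (9, 9),
) -> SSFAResult:
    """Level, fill, optionally crop, and compute all four SSFA attributes."""
    from .surfaces import fill_missing

    work = hmap
    if crop is not None:
        work = extract_region(work, crop)
    work = level(work)
    if not work.fully_measured:
        work = fill_missing(work)
    curve = relative_area_curve(work)
    a, smc = asfc_smc(curve, window=min(window, len(curve)))
    ep, direction, rose = eplsar(work, length_scale=length_scale, angle_step=angle_step)
    try:
        h9 = hasfc(work, grid=hasfc_grid, window=window)
    except ValueError:
        h9 = float("nan")
    return SSFAResult(
        asfc=a,
        smc=smc,
        eplsar=ep,
        eplsar_direction=direction,
        texture_direction=texture_direction(direction),
        hasfc9=h9,
        relative_area_curve=curve,
        rose=rose,
    )
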