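"""Synthetic crowns, wear surfaces, feature populations and band transects.

Every generator carries machine-readable ground truth so each pipeline
stage can be tested against known quantities without any scanned data:
crowns have closed-form volumes (and closed-form removed volumes for plane
cuts), surfaces retain the feature list and pit fraction they were stamped
with, and band transects know their day count, width trend and
working/balancing asymmetry.  All randomness flows through a caller-held
seed; the same seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .microwear import MicrowearFeature
from .surfaces import BandTransect, CrownMesh, HeightMap

# ---------------------------------------------------------------------------
# crowns
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCrownSpec:
    """Parametric tooth crown with an optional horizontal wear cut.

    Shapes: ``cone`` (radius, height), ``hemisphere`` (radius), and
    ``ellipsoid`` (semi-axes ``radius``, ``radius``, ``height``).  A wear
    cut is a horizontal plane at ``cut_height`` (same units, mm) removing
    everything above it, or a target ``removal_fraction`` of the complete
    volume from which the plane height is solved in closed form.  Denticle
    ornamentation (radial sinusoidal bumps) is available for generating
    complex occlusal topography but forfeits the closed-form volume; the
    truth volume is then measured on the watertight mesh itself.
    """

    shape: str = "cone"
    radius: float = 3.0  # mm
    height: float = 8.0  # mm; ignored for hemisphere
    cut_height: float | None = None
    removal_fraction: float | None = None
    denticle_count: int = 0
    denticle_amplitude: float = 0.0  # mm
    sections: int = 128
    seed: int = 0


@dataclass
class CrownTruth:
    v_complete: float  # mm³
    v_removed: float  # mm³
    removal_fraction: float
    analytic: bool  # True when both volumes are closed-form


def _cone_mesh(r: float, h: float, sections: int) -> trimesh.Trimesh:
    return trimesh.creation.cone(radius=r, height=h, sections=sections)


def _hemisphere_mesh(r: float, stacks: int, sectors: int) -> trimesh.Trimesh:
    """UV hemisphere (z >= 0) closed with a base disk."""
    phis = np.linspace(0, np.pi / 2, stacks + 1)[1:]  # skip the apex ring
    thetas = np.linspace(0, 2 * np.pi, sectors, endpoint=False)
    verts = [[0.0, 0.0, r]]
    for phi in phis:
        for th in thetas:
            verts.append(
                [r * np.sin(phi) * np.cos(th), r * np.sin(phi) * np.sin(th), r * np.cos(phi)]
            )
    verts.append([0.0, 0.0, 0.0])  # base center
    verts = np.asarray(verts)
    base_center = len(verts) - 1
    faces = []
    ring = lambda i, j: 1 + i * sectors + (j % sectors)  # noqa: E731
    for j in range(sectors):  # apex fan
        faces.append([0, ring(0, j), ring(0, j + 1)])
    for i in range(stacks - 1):
        for j in range(sectors):
            a, b = ring(i, j), ring(i, j + 1)
            c, d = ring(i + 1, j), ring(i + 1, j + 1)
            faces.append([a, c, d])
            faces.append([a, d, b])
    last = stacks - 1
    for j in range(sectors):  # base disk
        faces.append([base_center, ring(last, j + 1), ring(last, j)])
    mesh = trimesh.Trimesh(verts, np.asarray(faces), process=False)
    trimesh.repair.fix_normals(mesh)
    return mesh


def _complete_volume(spec: SyntheticCrownSpec) -> float:
    if spec.shape == "cone":
        return np.pi * spec.radius**2 * spec.height / 3.0
    if spec.shape == "hemisphere":
        return 2.0 * np.pi * spec.radius**3 / 3.0
    if spec.shape == "ellipsoid":
        return 4.0 * np.pi * spec.radius**2 * spec.height / 3.0
    raise ValueError(f"unknown crown shape {spec.shape!r}")


def _crown_apex(spec: SyntheticCrownSpec) -> float:
    return spec.radius if spec.shape == "hemisphere" else spec.height


def _removed_volume_above(spec: SyntheticCrownSpec, zc: float) -> float:
    """Closed-form volume of the shape above the horizontal plane z = zc."""
    if spec.shape == "cone":
        h = spec.height
        return _complete_volume(spec) * ((h - zc) / h) ** 3
    if spec.shape == "hemisphere":
        r = spec.radius
        hc = r - zc  # spherical-cap height
        return np.pi * hc**2 * (3 * r - hc) / 3.0
    if spec.shape == "ellipsoid":
        # ellipsoid cap: sphere cap scaled by (a/R)(b/R) in x, y
        c = spec.height
        if zc <= -c:
            return _complete_volume(spec)
        hc = c - zc
        sphere_cap = np.pi * hc**2 * (3 * c - hc) / 3.0
        return sphere_cap * (spec.radius / c) ** 2
    raise ValueError(f"unknown crown shape {spec.shape!r}")


def _solve_cut_height(spec: SyntheticCrownSpec, fraction: float) -> float:
    """Horizontal-plane height removing the requested volume fraction."""
    v = _complete_volume(spec)
    target = fraction * v
    if spec.shape == "cone":
        return spec.height * (1.0 - fraction ** (1.0 / 3.0))
    # hemisphere / ellipsoid: monotone in zc, bisect
    lo = -spec.height if spec.shape == "ellipsoid" else 0.0
    hi = _crown_apex(spec)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _removed_volume_above(spec, mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def make_crown(spec: SyntheticCrownSpec) -> tuple[CrownMesh, CrownMesh | None, CrownTruth]:
    """Build (complete, worn, truth) for a synthetic crown.

    The worn crown is the complete mesh sliced by the horizontal wear plane
    and capped; it is None when the spec has no cut.
    """
    if spec.shape == "cone":
        tm = _cone_mesh(spec.radius, spec.height, spec.sections)
    elif spec.shape == "hemisphere":
        tm = _hemisphere_mesh(spec.radius, max(spec.sections // 4, 8), spec.sections)
    elif spec.shape == "ellipsoid":
        tm = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        tm.apply_scale([spec.radius, spec.radius, spec.height])
    else:
        raise ValueError(f"unknown crown shape {spec.shape!r}")

    analytic = True
    if spec.denticle_count > 0 and spec.denticle_amplitude > 0:
        v = tm.vertices.copy()
        th = np.arctan2(v[:, 1], v[:, 0])
        rad = np.hypot(v[:, 0], v[:, 1])
        relief = 1.0 + spec.denticle_amplitude * np.sin(spec.denticle_count * th) * (
            rad / max(rad.max(), 1e-12)
        )
        v[:, 0] *= relief
        v[:, 1] *= relief
        tm = trimesh.Trimesh(v, tm.faces.copy(), process=False)
        analytic = False
    if not tm.is_watertight:
        raise ValueError("generated crown mesh is not watertight")

    v_complete = _complete_volume(spec) if analytic else float(abs(tm.volume))

    zc = spec.cut_height
    if zc is None and spec.removal_fraction is not None:
        if not 0.0 < spec.removal_fraction < 1.0:
            raise ValueError("removal_fraction must be in (0, 1)")
        zc = _solve_cut_height(spec, spec.removal_fraction)

    worn = None
    v_removed = 0.0
    if zc is not None:
        apex = float(tm.vertices[:, 2].max())
        zlo = float(tm.vertices[:, 2].min())
        if not zlo < zc < apex:
            raise ValueError(f"cut height {zc} outside crown extent ({zlo}, {apex})")
        worn_tm = trimesh.intersections.slice_mesh_plane(
            tm, plane_normal=[0.0, 0.0, -1.0], plane_origin=[0.0, 0.0, zc], cap=False
        )
        worn_tm.merge_vertices()  # the slice duplicates cut-line vertices
        worn = CrownMesh(
            np.asarray(worn_tm.vertices), np.asarray(worn_tm.faces), label="worn"
        )
        # close the planar cut with the package's own fan cap
        from .wear import boundary_loops, cap_loop

        for loop in boundary_loops(worn):
            worn = cap_loop(worn, loop)
        worn_tm = worn.to_trimesh()
        v_removed = (
            _removed_volume_above(spec, zc) if analytic else v_complete - float(abs(worn_tm.volume))
        )

    complete = CrownMesh(np.asarray(tm.vertices), np.asarray(tm.faces), label="complete")
    truth = CrownTruth(
        v_complete=float(v_complete),
        v_removed=float(v_removed),
        removal_fraction=float(v_removed / v_complete),
        analytic=analytic,
    )
    return complete, worn, truth


# ---------------------------------------------------------------------------
# wear surfaces
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSurfaceSpec:
    """Confocal-like wear facet: fractal background + stamped features.

    Defaults mirror a 20x confocal field: 0.83 µm lateral spacing.  Scratch
    orientations are drawn from a von Mises distribution on doubled (axial)
    angles around ``scratch_orientation_deg`` with concentration
    ``scratch_kappa`` (0 = isotropic).  ``pit_fraction`` of the ``n_features``
    are pits.  ``missing_fraction`` of cells are masked non-measured.
    """

    n: int = 256  # grid cells per side
    spacing: float = 0.83  # µm
    n_features: int = 120
    pit_fraction: float = 0.75
    scratch_orientation_deg: float = 30.0
    scratch_kappa: float = 0.0
    scratch_length_um: tuple[float, float] = (40.0, 120.0)
    scratch_width_um: tuple[float, float] = (2.0, 6.0)
    scratch_depth_um: float = 0.6
    pit_radius_um: tuple[float, float] = (2.0, 8.0)
    pit_depth_um: float = 0.8
    hurst: float = 0.7
    background_rms_um: float = 0.15
    missing_fraction: float = 0.0


@dataclass
class SurfaceTruth:
    features: pd.DataFrame  # x1,y1,x2,y2,width_um,kind
    pit_fraction: float
    dominant_orientation_deg: float
    background_rms_um: float


def fractal_background(n: int, hurst: float, rms: float, rng: np.random.Generator) -> np.ndarray:
    """Self-affine field by spectral synthesis: amplitude ~ k^-(hurst + 1)."""
    kx = np.fft.fftfreq(n)[None, :]
    ky = np.fft.fftfreq(n)[:, None]
    k = np.hypot(kx, ky)
    k[0, 0] = np.inf  # zero the mean
    amp = k ** -(hurst + 1.0)
    phase = rng.uniform(0, 2 * np.pi, (n, n))
    spec = amp * np.exp(1j * phase)
    z = np.fft.ifft2(spec).real
    z -= z.mean()
    sd = z.std()
    return z * (rms / sd) if sd > 0 else z


def _stamp_gaussian_segment(z, x1, y1, x2, y2, sigma, depth, spacing):
    """Subtract a groove: depth·exp(-d²/2σ²) of distance d to the segment."""
    n = z.shape[0]
    pad = 3.0 * sigma
    j0 = max(int((min(x1, x2) - pad) / spacing), 0)
    j1 = min(int((max(x1, x2) + pad) / spacing) + 2, n)
    i0 = max(int((min(y1, y2) - pad) / spacing), 0)
    i1 = min(int((max(y1, y2) + pad) / spacing) + 2, n)
    if i0 >= i1 or j0 >= j1:
        return
    jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
    px, py = jj * spacing, ii * spacing
    vx, vy = x2 - x1, y2 - y1
    ll = vx * vx + vy * vy
    if ll == 0:
        t = np.zeros_like(px)
    else:
        t = np.clip(((px - x1) * vx + (py - y1) * vy) / ll, 0.0, 1.0)
    d = np.hypot(px - (x1 + t * vx), py - (y1 + t * vy))
    z[i0:i1, j0:j1] -= depth * np.exp(-0.5 * (d / sigma) ** 2)


def make_surface(
    spec: SyntheticSurfaceSpec, rng: np.random.Generator | int = 0
) -> tuple[HeightMap, SurfaceTruth]:
    """Generate a wear-facet height map and its ground truth."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n, sp = spec.n, spec.spacing
    extent = (n - 1) * sp
    z = fractal_background(n, spec.hurst, spec.background_rms_um, rng)

    rows = []
    is_pit = rng.random(spec.n_features) < spec.pit_fraction
    for k in range(spec.n_features):
        if is_pit[k]:
            r = rng.uniform(*spec.pit_radius_um)
            cx, cy = rng.uniform(0.05 * extent, 0.95 * extent, 2)
            _stamp_gaussian_segment(z, cx, cy, cx, cy, r / 2.0, spec.pit_depth_um, sp)
            # digitized as a near-equant segment of length ~ diameter
            rows.append(
                dict(x1=cx - r, y1=cy, x2=cx + r, y2=cy, width_um=2 * r, kind="pit")
            )
        else:
            length = rng.uniform(*spec.scratch_length_um)
            width = rng.uniform(*spec.scratch_width_um)
            if spec.scratch_kappa > 0:
                ang2 = rng.vonmises(np.radians(2 * spec.scratch_orientation_deg), spec.scratch_kappa)
                theta = 0.5 * (ang2 % (2 * np.pi))
            else:
                theta = rng.uniform(0, np.pi)
            cx, cy = rng.uniform(0.1 * extent, 0.9 * extent, 2)
            dx, dy = 0.5 * length * np.cos(theta), 0.5 * length * np.sin(theta)
            _stamp_gaussian_segment(
                z, cx - dx, cy - dy, cx + dx, cy + dy, width / 4.0, spec.scratch_depth_um, sp
            )
            rows.append(
                dict(
                    x1=cx - dx, y1=cy - dy, x2=cx + dx, y2=cy + dy, width_um=width, kind="scratch"
                )
            )

    # stamping treated the row index as +y; flip so row 0 = max y
    z = z[::-1].copy()

    mask = np.ones((n, n), dtype=bool)
    if spec.missing_fraction > 0:
        holes = rng.random((n, n)) < spec.missing_fraction
        mask &= ~holes
        z = np.where(mask, z, np.nan)

    truth = SurfaceTruth(
        features=pd.DataFrame(rows),
        pit_fraction=float(is_pit.mean()) if spec.n_features else 0.0,
        dominant_orientation_deg=spec.scratch_orientation_deg,
        background_rms_um=spec.background_rms_um,
    )
    return HeightMap(z, dx=sp, dy=sp, mask=mask, label="synthetic"), truth


def make_feature_population(
    pit_fraction: float,
    n: int,
    rng: np.random.Generator | int = 0,
    micrograph_id: str = "synthetic",
) -> tuple[list[MicrowearFeature], float]:
    """Digitized-feature population with a known expected pit fraction.

    Pits draw length:width ratios in [1, 3), scratches in [5, 20), both
    safely inside their class definitions; sizes stay below the macrowear
    gate.  Returns the features and the realised pit fraction.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    is_pit = rng.random(n) < pit_fraction
    feats = []
    for k in range(n):
        if is_pit[k]:
            width = rng.uniform(2.0, 15.0)
            length = width * rng.uniform(1.0, 3.0)
        else:
            width = rng.uniform(1.0, 6.0)
            length = width * rng.uniform(5.0, 20.0)
        cx, cy = rng.uniform(100, 500), rng.uniform(100, 350)
        theta = rng.uniform(0, np.pi)
        dx, dy = 0.5 * length * np.cos(theta), 0.5 * length * np.sin(theta)
        feats.append(
            MicrowearFeature(
                p1=(cx - dx, cy - dy),
                p2=(cx + dx, cy + dy),
                width=width,
                micrograph_id=micrograph_id,
            )
        )
    return feats, float(is_pit.mean())


def make_feature_micrograph(
    n_px: int,
    spacing: float,
    n_features: int,
    pit_fraction: float,
    rng: np.random.Generator | int = 0,
) -> tuple[np.ndarray, float]:
    """Binary micrograph of non-overlapping ellipses with known composition.

    Pits are drawn with axis ratio < 4, scratches > 4.  Features are placed
    on a coarse grid so components never merge.  Returns the mask and the
    realised pit fraction.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    img = np.zeros((n_px, n_px), dtype=bool)
    cell = n_px // int(np.ceil(np.sqrt(n_features)))
    slots = [
        (i, j)
        for i in range(n_px // cell)
        for j in range(n_px // cell)
        if (i + 1) * cell <= n_px and (j + 1) * cell <= n_px
    ]
    rng.shuffle(slots)
    is_pit = rng.random(n_features) < pit_fraction
    yy, xx = np.mgrid[0:n_px, 0:n_px]
    placed = 0
    for k in range(min(n_features, len(slots))):
        i, j = slots[k]
        cy, cx = (i + 0.5) * cell, (j + 0.5) * cell
        if is_pit[k]:
            b = rng.uniform(2.0, 0.18 * cell)
            a = b * rng.uniform(1.0, 2.5)
        else:
            b = rng.uniform(1.0, 0.06 * cell)
            a = b * rng.uniform(6.0, 0.45 * cell / b)
        theta = rng.uniform(0, np.pi)
        c, s = np.cos(theta), np.sin(theta)
        u = (xx - cx) * c + (yy - cy) * s
        v = -(xx - cx) * s + (yy - cy) * c
        img |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
        placed += 1
    return img, float(is_pit[:placed].mean())


# ---------------------------------------------------------------------------
# band transects
# ---------------------------------------------------------------------------


@dataclass
class SyntheticBandSpec:
    """Daily-band transect: n_days bands of known mean width and asymmetry."""

    n_days: int = 126
    mean_width: float = 25.0  # µm (balancing side)
    width_cv: float = 0.0
    trend: float = 0.0  # fractional width change per band index
    working_ratio: float = 1.0  # working mean width / balancing mean width
    complete: bool = True


@dataclass
class BandTruth:
    n_days: int
    balancing_mean_width: float
    working_mean_width: float
    ratio: float
    trend_slope: float  # µm per band index, balancing side


def _band_widths(spec: SyntheticBandSpec, mean: float, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_days
    idx = np.arange(n)
    base = mean * (1.0 + spec.trend * (idx - (n - 1) / 2.0))
    if spec.width_cv > 0:
        sigma = np.sqrt(np.log(1 + spec.width_cv**2))
        base = base * rng.lognormal(-0.5 * sigma**2, sigma, n)
    if np.any(base <= 0):
        raise ValueError("band spec produces non-positive widths; reduce trend/cv")
    return base


def make_bands(
    spec: SyntheticBandSpec, rng: np.random.Generator | int = 0
) -> tuple[BandTransect, BandTransect, BandTruth]:
    """(working, balancing, truth) transects with prescribed asymmetry."""
    if spec.n_days < 2:
        raise ValueError("n_days must be >= 2")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    bal_w = _band_widths(spec, spec.mean_width, rng)
    wrk_w = _band_widths(spec, spec.mean_width * spec.working_ratio, rng)
    balancing = BandTransect(
        np.concatenate([[0.0], np.cumsum(bal_w)]),
        side="balancing",
        complete=spec.complete,
        specimen="synthetic",
    )
    working = BandTransect(
        np.concatenate([[0.0], np.cumsum(wrk_w)]),
        side="working",
        complete=spec.complete,
        specimen="synthetic",
    )
    truth = BandTruth(
        n_days=spec.n_days,
        balancing_mean_width=float(bal_w.mean()),
        working_mean_width=float(wrk_w.mean()),
        ratio=float(wrk_w.mean() / bal_w.mean()),
        trend_slope=spec.mean_width * spec.trend,
    )
    return working, balancing, truth


# ---------------------------------------------------------------------------
# the two-taxon study suite
# ---------------------------------------------------------------------------

#: Pit fractions of the two emulated feature populations (ankylosaur-like
#: and rhabdodontid-like browsers), used by the acceptance suite.
SUITE_PIT_FRACTIONS = {"taxon_A": 0.7267, "taxon_B": 0.8254}


def two_taxon_suite(
    seed: int = 0, n_features: int = 10_000, n_surfaces: int = 4
) -> dict[str, dict]:
    """Two taxon-labelled populations of pit-dominated, low-anisotropy data.

    For each taxon: a large digitized-feature population at its pit
    fraction, plus ``n_surfaces`` small confocal-like surfaces with high pit
    density and near-isotropic scratches (the browser-like texture regime).
    """
    out = {}
    for i, (taxon, pf) in enumerate(sorted(SUITE_PIT_FRACTIONS.items())):
        rng = np.random.default_rng(seed + 7919 * i)
        feats, realised = make_feature_population(pf, n_features, rng, micrograph_id=taxon)
        surfaces = []
        for s in range(n_surfaces):
            sspec = SyntheticSurfaceSpec(
                n=128,
                n_features=60,
                pit_fraction=pf,
                scratch_kappa=0.0,  # isotropic scratches -> low anisotropy
                background_rms_um=0.1 + 0.1 * s,  # complexity spans a range
            )
            surfaces.append(make_surface(sspec, rng))
        out[taxon] = {
            "features": feats,
            "pit_fraction_nominal": pf,
            "pit_fraction_realised": realised,
            "surfaces": surfaces,
        }
    return out
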