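"""Readers, writers, and in-memory carriers for all four input kinds.

Conventions used throughout the toolkit:

* meshes are stored in millimetres with the occlusal surface pointing
  toward +Z (apicobasal axis defaults to +Z);
* height maps are stored in micrometres, image-like: row 0 carries the
  maximum y coordinate, storage is row-major, values are registered at
  cell centers;
* micrograph feature tables and incremental-band transects travel as CSV.

Unit conversion happens only at these I/O boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from scipy.interpolate import RBFInterpolator

from .errors import EmptyDataError, FormatError, LatticeError
from .microwear import MicrowearFeature, features_from_frame, features_to_frame


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CrownMesh:
    """Oriented triangle mesh of a tooth crown (mm, occlusal = +Z)."""

    vertices: np.ndarray  # (n, 3) float, mm
    faces: np.ndarray  # (m, 3) int
    apicobasal_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    label: str = ""

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        ax = np.asarray(self.apicobasal_axis, dtype=float)
        self.apicobasal_axis = ax / np.linalg.norm(ax)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face indices out of range")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @property
    def is_watertight(self) -> bool:
        return self.to_trimesh().is_watertight

    def signed_volume(self) -> float:
        """Divergence-theorem signed volume (mm³); positive for outward winding."""
        v = self.vertices
        t = v[self.faces]
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)


@dataclass
class HeightMap:
    """Regular elevation grid in µm with a measured-data mask.

    ``heights[0, :]`` is the row with maximum y; ``origin`` is the (x, y)
    of the center of cell (0, 0).  ``mask`` is True where measured.
    """

    heights: np.ndarray
    dx: float
    dy: float
    mask: np.ndarray | None = None
    origin: tuple[float, float] = (0.0, 0.0)
    label: str = ""

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D grid")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("dx and dy must be positive")
        if self.mask is None:
            self.mask = np.isfinite(self.heights)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.heights.shape:
            raise ValueError("mask shape must match heights")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def fully_measured(self) -> bool:
        return bool(self.mask.all())

    def cell_xy(self) -> tuple[np.ndarray, np.ndarray]:
        """x and y coordinates of every cell center (same shape as heights)."""
        ny, nx = self.heights.shape
        x = self.origin[0] + np.arange(nx) * self.dx
        y = self.origin[1] - np.arange(ny) * self.dy
        return np.meshgrid(x, y)

    def copy(self) -> "HeightMap":
        return HeightMap(
            self.heights.copy(), self.dx, self.dy, self.mask.copy(), tuple(self.origin), self.label
        )


@dataclass
class FeatureTable:
    """Digitized microwear features from one or more micrographs."""

    features: list[MicrowearFeature]
    field_of_view: tuple[float, float] = (637.0, 477.0)  # µm
    micrograph_id: str = ""

    def __post_init__(self):
        w, h = self.field_of_view
        for f in self.features:
            mx, my = f.midpoint
            if not (0 <= mx <= w and 0 <= my <= h):
                raise ValueError(
                    f"feature midpoint ({mx:.1f}, {my:.1f}) outside field of view {self.field_of_view}"
                )

    def __len__(self):
        return len(self.features)

    def to_frame(self) -> pd.DataFrame:
        return features_to_frame(self.features)


@dataclass
class BandTransect:
    """Ordered incremental-band boundary positions along one dentine transect.

    Positions run in µm from the enamel–dentine junction toward the pulp
    cavity.  ``complete`` is True only when the transect spans first-formed
    dentine all the way to the pulp margin, in which case the band count is
    the tooth formation time in days rather than a minimum.
    """

    boundaries: np.ndarray
    side: str = "unspecified"  # working | balancing | unspecified
    section_plane: str = "transverse"  # transverse | longitudinal | coronal
    complete: bool = True
    specimen: str = ""

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.boundaries.size < 2:
            raise ValueError("a transect needs at least 2 boundaries")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundary positions must be strictly increasing")
        if np.any(self.boundaries < 0):
            raise ValueError("boundary positions must be non-negative")

    @property
    def n_bands(self) -> int:
        return len(self.boundaries) - 1


# ---------------------------------------------------------------------------
# mesh I/O
# ---------------------------------------------------------------------------

_MESH_EXT = {".ply", ".obj", ".stl"}


def read_mesh(path: str | Path, units: str = "mm", label: str | None = None) -> CrownMesh:
    """Load a PLY/OBJ/STL crown mesh.

    ``units='µm'`` (or ``'um'``) rescales coordinates to millimetres.
    Degenerate (zero-area) faces are dropped with a warning.  The winding is
    made consistent and flipped if the enclosed signed volume is negative.
    """
    path = Path(path)
    if path.suffix.lower() not in _MESH_EXT:
        raise FormatError(f"unsupported mesh format: {path.suffix}")
    try:
        tm = trimesh.load_mesh(path, process=False)
    except Exception as exc:  # pragma: no cover - trimesh error strings vary
        raise FormatError(f"could not read mesh {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise FormatError(f"{path} contains no triangle data")

    areas = tm.area_faces
    n_degenerate = int((areas <= 0).sum())
    if n_degenerate:
        warnings.warn(f"{path.name}: dropping {n_degenerate} degenerate faces")
        tm.update_faces(areas > 0)
    trimesh.repair.fix_normals(tm)

    verts = np.asarray(tm.vertices, dtype=float)
    if units in ("µm", "um"):
        verts = verts / 1000.0
    elif units != "mm":
        raise ValueError(f"units must be 'mm' or 'µm', got {units!r}")

    mesh = CrownMesh(verts, np.asarray(tm.faces), label=label or path.stem)
    if mesh.is_watertight and mesh.signed_volume() < 0:
        mesh.faces = mesh.faces[:, ::-1]
    return mesh


def write_mesh(mesh: CrownMesh, path: str | Path) -> None:
    mesh.to_trimesh().export(Path(path))


def ensure_watertight(mesh: CrownMesh) -> CrownMesh:
    """Validate the every-edge-shared-twice property; raise otherwise."""
    from .wear import boundary_loops  # local import to avoid a cycle

    loops = boundary_loops(mesh)
    if loops:
        from .errors import WatertightError

        raise WatertightError(f"mesh has {len(loops)} boundary loop(s)", loops=loops)
    if mesh.signed_volume() < 0:
        mesh = CrownMesh(
            mesh.vertices, mesh.faces[:, ::-1], mesh.apicobasal_axis, mesh.label
        )
    return mesh


# ---------------------------------------------------------------------------
# height-map I/O
# ---------------------------------------------------------------------------

_SENTINEL = "nan"


def read_heightmap(path: str | Path, dialect: str = "matrix") -> HeightMap:
    """Read a height map from a plain-text file.

    ``matrix`` dialect: a header line ``# dx=<µm> dy=<µm> x0=<µm> y0=<µm>``
    followed by rows of elevations (row 0 = maximum y); missing cells are
    the sentinel token ``nan``.  ``xyz`` dialect: whitespace-separated
    ``x y z`` triples on a regular lattice (z may be ``nan``).
    """
    path = Path(path)
    if dialect == "matrix":
        return _read_matrix(path)
    if dialect in ("xyz", "xyz-grid"):
        return _read_xyz(path)
    raise ValueError(f"unknown height-map dialect {dialect!r}")


def _read_matrix(path: Path) -> HeightMap:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise FormatError(f"{path}: matrix dialect requires a '# dx=... dy=...' header")
        kv = {}
        for tok in header.lstrip("#").split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                kv[k] = float(v)
        if "dx" not in kv or "dy" not in kv:
            raise FormatError(f"{path}: header must provide dx and dy")
        try:
            heights = np.loadtxt(fh, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    mask = np.isfinite(heights)
    if not mask.any():
        raise EmptyDataError(f"{path}: all cells are non-measured")
    return HeightMap(
        heights,
        kv["dx"],
        kv["dy"],
        mask,
        origin=(kv.get("x0", 0.0), kv.get("y0", 0.0)),
        label=path.stem,
    )


def _read_xyz(path: Path, rtol: float = 1e-6) -> HeightMap:
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] != 3:
        raise FormatError(f"{path}: xyz dialect needs three columns")
    xs = np.unique(data[:, 0])
    ys = np.unique(data[:, 1])
    if len(xs) < 2 or len(ys) < 2:
        raise LatticeError(f"{path}: fewer than 2 distinct x or y values")
    dxs, dys = np.diff(xs), np.diff(ys)
    scale = max(xs.max() - xs.min(), ys.max() - ys.min())
    if dxs.max() - dxs.min() > rtol * scale or dys.max() - dys.min() > rtol * scale:
        raise LatticeError(f"{path}: points do not form a regular lattice")
    if len(data) != len(xs) * len(ys):
        raise LatticeError(f"{path}: lattice is not completely sampled")
    dx, dy = float(dxs.mean()), float(dys.mean())
    ix = np.searchsorted(xs, data[:, 0])
    iy = np.searchsorted(ys, data[:, 1])
    heights = np.full((len(ys), len(xs)), np.nan)
    heights[len(ys) - 1 - iy, ix] = data[:, 2]  # row 0 = max y
    mask = np.isfinite(heights)
    if not mask.any():
        raise EmptyDataError(f"{path}: all cells are non-measured")
    return HeightMap(heights, dx, dy, mask, origin=(float(xs[0]), float(ys[-1])), label=path.stem)


def write_heightmap(hmap: HeightMap, path: str | Path, dialect: str = "matrix") -> None:
    path = Path(path)
    if dialect == "matrix":
        vals = np.where(hmap.mask, hmap.heights, np.nan)
        with open(path, "w") as fh:
            fh.write(
                f"# dx={hmap.dx!r} dy={hmap.dy!r} x0={hmap.origin[0]!r} y0={hmap.origin[1]!r}\n"
            )
            np.savetxt(fh, vals, fmt="%.17g")
    elif dialect in ("xyz", "xyz-grid"):
        X, Y = hmap.cell_xy()
        vals = np.where(hmap.mask, hmap.heights, np.nan)
        np.savetxt(path, np.column_stack([X.ravel(), Y.ravel(), vals.ravel()]), fmt="%.17g")
    else:
        raise ValueError(f"unknown height-map dialect {dialect!r}")


# ---------------------------------------------------------------------------
# feature-table and transect I/O (CSV)
# ---------------------------------------------------------------------------


def read_feature_table(path: str | Path, field_of_view=(637.0, 477.0)) -> FeatureTable:
    """CSV columns: micrograph_id,x1,y1,x2,y2,width_um."""
    df = pd.read_csv(path)
    required = {"micrograph_id", "x1", "y1", "x2", "y2", "width_um"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: feature CSV must have columns {sorted(required)}")
    return FeatureTable(features_from_frame(df), field_of_view=field_of_view)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_band_transects(path: str | Path) -> list[BandTransect]:
    """CSV columns: specimen,side,section_plane,position_um,complete."""
    df = pd.read_csv(path)
    required = {"specimen", "side", "section_plane", "position_um", "complete"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: transect CSV must have columns {sorted(required)}")
    out = []
    for (spec, side, plane), grp in df.groupby(["specimen", "side", "section_plane"], sort=True):
        out.append(
            BandTransect(
                boundaries=np.sort(grp["position_um"].to_numpy(dtype=float)),
                side=str(side),
                section_plane=str(plane),
                complete=bool(grp["complete"].iloc[0]),
                specimen=str(spec),
            )
        )
    return out


def write_band_transects(transects: list[BandTransect], path: str | Path) -> None:
    rows = []
    for t in transects:
        for pos in t.boundaries:
            rows.append(
                dict(
                    specimen=t.specimen,
                    side=t.side,
                    section_plane=t.section_plane,
                    position_um=pos,
                    complete=t.complete,
                )
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# missing-data fill
# ---------------------------------------------------------------------------


def fill_missing(
    hmap: HeightMap, kernel: str = "thin_plate_spline", neighbors: int = 64, clamp: bool = True
) -> HeightMap:
    """Fill non-measured cells with a smooth spline interpolant of neighbors.

    A thin-plate-spline radial-basis interpolant (configurable kernel) is
    fitted to the nearest measured samples of each hole.  Measured cells are
    never touched, so the operation is idempotent on fully measured maps.
    With ``clamp`` the fill is bounded to the measured range ± 10% of the
    range, which keeps an overshooting interpolant from inventing extrema.
    """
    if not hmap.mask.any():
        raise EmptyDataError("cannot fill a map with no measured cells")
    if hmap.fully_measured:
        return hmap.copy()

    out = hmap.copy()
    ny, nx = hmap.shape
    ii, jj = np.indices((ny, nx))
    pts = np.column_stack([jj[hmap.mask] * hmap.dx, ii[hmap.mask] * hmap.dy])
    vals = hmap.heights[hmap.mask]
    holes = np.column_stack([jj[~hmap.mask] * hmap.dx, ii[~hmap.mask] * hmap.dy])
    interp = RBFInterpolator(
        pts, vals, kernel=kernel, neighbors=min(neighbors, len(vals)), degree=1
    )
    filled = interp(holes)
    if clamp:
        lo, hi = vals.min(), vals.max()
        pad = 0.1 * (hi - lo)
        filled = np.clip(filled, lo - pad, hi + pad)
    out.heights[~hmap.mask] = filled
    out.mask[:] = True
    return out
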