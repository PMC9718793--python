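import numpy as np
import pytest

from dentoproxy.surfaces import HeightMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def plane_map():
    """z = 5 + 2x - 3y on a 40x40 unit-spaced grid."""
    x, y = np.meshgrid(np.arange(40, dtype=float), np.arange(40, dtype=float))
    return HeightMap(5 + 2 * x - 3 * y, 1.0, 1.0)


@pytest.fixture
def flat_map():
    return HeightMap(np.zeros((128, 128)), 0.83, 0.83)


def brute_force_patch_count(bins: np.ndarray, min_patch_size: int) -> tuple[int, dict]:
    """Independent flood-fill (BFS, 4-neighbor) patch counter."""
    ny, nx = bins.shape
    visited = np.zeros_like(bins, dtype=bool)
    per_bin = {b: 0 for b in range(8)}
    total = 0
    for i in range(ny):
        for j in range(nx):
            b = bins[i, j]
            if visited[i, j] or b < 0:
                continue
            stack, size = [(i, j)], 0
            visited[i, j] = True
            while stack:
                ci, cj = stack.pop()
                size += 1
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ni, nj = ci + di, cj + dj
                    if 0 <= ni < ny and 0 <= nj < nx and not visited[ni, nj] and bins[ni, nj] == b:
                        visited[ni, nj] = True
                        stack.append((ni, nj))
            if size >= min_patch_size:
                per_bin[b] += 1
                total += 1
    return total, per_bin


def ray_heights(mesh, xs, ys):
    """Max-z vertical-ray elevations by Möller–Trumbore over all triangles."""
    tri = mesh.vertices[mesh.faces]
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    out = np.full(len(xs), -np.inf)
    d = np.array([0.0, 0.0, -1.0])
    for k, (x, y) in enumerate(zip(xs, ys)):
        o = np.array([x, y, 1e6])
        p = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, p)
        ok = np.abs(det) > 1e-14
        t = o - v0
        u = np.einsum("ij,ij->i", t, p) / np.where(ok, det, 1.0)
        q = np.cross(t, e1)
        v = np.dot(q, d) / np.where(ok, det, 1.0)
        hit = ok & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12)
        if hit.any():
            dist = np.einsum("ij,ij->i", e2[hit], q[hit]) / det[hit]
            out[k] = (1e6 - dist).max()
    return out
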