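"""Bumpy-plane geometry: height fields, principal curvatures, shape index.

The stimulus surface is a smooth bumpy plane viewed fronto-parallel, i.e. a
graph surface z = f(x, y) with z pointing toward the observer.  Local shape is
summarised by the Koenderink shape index

    s = -(2/pi) * atan2(k1 + k2, k1 - k2),      k1 >= k2,

a scale-free statistic in [-1, 1]: symmetric convexities (bumps toward the
viewer) map to -1, symmetric saddles to 0, symmetric concavities to +1.
Convex-outward principal curvature is taken positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HeightField",
    "TriMesh",
    "PrincipalCurvatures",
    "ShapeIndexMap",
    "RegionClassMap",
    "generate_bumpy_heightfield",
    "load_mesh_obj",
    "resample_to_heightfield",
    "principal_curvatures",
    "shape_index",
    "classify_region",
    "write_heightfield_table",
    "write_grayscale_png",
]

# region-class integer codes
CONVEX, SADDLE, CONCAVE = -1, 0, 1

#: |s| below this bound is classed a saddle; equal thirds of the [-1, 1] range.
REGION_THRESHOLD = 1.0 / 3.0


@dataclass(frozen=True)
class HeightField:
    """Gridded surface relief z = f(x, y).

    ``heights[iy, ix]`` is the elevation at ``(x, y) = (ix, iy) * spacing``
    (corner origin) in model units.  The grid is treated as laterally periodic
    by the renderer, which matches the FFT construction used by
    :func:`generate_bumpy_heightfield`.
    """

    heights: np.ndarray
    spacing: float
    origin_at_center: bool = False

    def __post_init__(self):
        h = np.asarray(self.heights, dtype=float)
        if h.ndim != 2:
            raise ValueError("heights must be a 2-D grid")
        if not np.all(np.isfinite(h)):
            raise ValueError("heights must be finite")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "heights", h)

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def extent(self) -> tuple[float, float]:
        """(Lx, Ly) of the periodic tile."""
        ny, nx = self.heights.shape
        return nx * self.spacing, ny * self.spacing

    def gradient_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Periodic central-difference slope grids (df/dx, df/dy)."""
        h, d = self.heights, self.spacing
        fx = (np.roll(h, -1, axis=1) - np.roll(h, 1, axis=1)) / (2 * d)
        fy = (np.roll(h, -1, axis=0) - np.roll(h, 1, axis=0)) / (2 * d)
        return fx, fy

    def interp(self, x, y, grid: np.ndarray | None = None) -> np.ndarray:
        """Periodic bilinear interpolation of ``grid`` (default: heights)."""
        g = self.heights if grid is None else grid
        ny, nx = g.shape
        u = np.asarray(x, dtype=float) / self.spacing
        v = np.asarray(y, dtype=float) / self.spacing
        i0 = np.floor(u).astype(np.int64)
        j0 = np.floor(v).astype(np.int64)
        du = u - i0
        dv = v - j0
        i0 %= nx
        j0 %= ny
        i1 = (i0 + 1) % nx
        j1 = (j0 + 1) % ny
        return (
            g[j0, i0] * (1 - du) * (1 - dv)
            + g[j0, i1] * du * (1 - dv)
            + g[j1, i0] * (1 - du) * dv
            + g[j1, i1] * du * dv
        )


@dataclass(frozen=True)
class TriMesh:
    """Triangulated surface mesh (vertices + face index triples)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be (m, 3) triangles")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)


@dataclass(frozen=True)
class PrincipalCurvatures:
    """Per-cell principal curvatures with k1 >= k2 (convex-outward positive)."""

    k1: np.ndarray
    k2: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        if np.any(self.k1[self.mask] < self.k2[self.mask] - 1e-12):
            raise ValueError("k1 < k2 violates the eigen-ordering contract")


@dataclass(frozen=True)
class ShapeIndexMap:
    s: np.ndarray
    mask: np.ndarray


@dataclass(frozen=True)
class RegionClassMap:
    """Qualitative shape classes and their display gray levels.

    ``classes`` holds -1 (convex), 0 (saddle), +1 (concave); ``gray`` is the
    linear display code (1 - s)/2, so concavities plot black and convexities
    light gray.
    """

    classes: np.ndarray
    gray: np.ndarray
    mask: np.ndarray


def generate_bumpy_heightfield(
    nx: int,
    amplitude: float = 0.5,
    correlation_length: float = 3.0,
    seed: int = 0,
    spacing: float = 0.25,
) -> HeightField:
    """Band-limited smooth random relief on an ``nx`` x ``nx`` periodic grid.

    White Gaussian noise is filtered in the Fourier domain with the kernel
    exp(-(pi * L * f)^2 / 2) (f in cycles per model unit, L the correlation
    length), which leaves essentially no power above f = 2/L, then rescaled
    to the requested RMS ``amplitude``.
    """
    if nx < 16:
        raise ValueError("nx must be >= 16")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if correlation_length <= spacing:
        raise ValueError("correlation_length must exceed the grid spacing")
    if amplitude == 0:
        return HeightField(np.zeros((nx, nx)), spacing)

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((nx, nx))
    f = np.fft.fftfreq(nx, d=spacing)
    f2 = f[None, :] ** 2 + f[:, None] ** 2
    kernel = np.exp(-((np.pi * correlation_length) ** 2) * f2 / 2.0)
    h = np.fft.ifft2(np.fft.fft2(noise) * kernel).real
    h -= h.mean()
    rms = h.std()
    if rms > 0:
        h *= amplitude / rms
    return HeightField(h, spacing)


def load_mesh_obj(path) -> TriMesh:
    """Load a triangulated Wavefront OBJ, dropping zero-area faces."""
    import trimesh

    mesh = trimesh.load(path, file_type="obj", force="mesh", process=False)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    if faces.size == 0:
        raise ValueError(f"{path}: mesh has no triangular faces")
    if faces.shape[1] != 3:
        raise ValueError(f"{path}: mesh is not triangulated")
    verts = np.asarray(mesh.vertices, dtype=float)
    # drop degenerate faces
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    area2 = np.linalg.norm(np.cross(b - a, c - a), axis=1)
    faces = faces[area2 > 1e-14]
    if faces.size == 0:
        raise ValueError(f"{path}: all faces degenerate")
    return TriMesh(verts, faces)


def resample_to_heightfield(mesh: TriMesh, nx: int) -> HeightField:
    """Sample mesh height on a regular grid by vertical ray casting.

    Each vertical ray is resolved by barycentric point-in-triangle tests in
    the xy projection (exact for graph-like meshes); where a ray crosses
    several faces the highest intersection wins.  The grid covers the
    mesh's xy bounding rectangle; cells the mesh does not cover inherit
    the nearest sampled height.
    """
    verts, faces = mesh.vertices, mesh.faces
    xmin, ymin = verts[:, 0].min(), verts[:, 1].min()
    xmax, ymax = verts[:, 0].max(), verts[:, 1].max()
    spacing = (xmax - xmin) / (nx - 1)
    if spacing <= 0:
        raise ValueError("mesh has zero x extent")
    ny = max(2, int(round((ymax - ymin) / spacing)) + 1)
    xs = xmin + spacing * np.arange(nx)
    ys = ymin + spacing * np.arange(ny)
    gx, gy = np.meshgrid(xs, ys)
    px, py = gx.ravel(), gy.ravel()
    heights = np.full(px.size, np.nan)
    eps = 1e-9 * max(xmax - xmin, ymax - ymin, 1.0)
    for tri in verts[faces]:
        (ax, ay, az), (bx, by, bz), (cx, cy, cz) = tri
        det = (by - cy) * (ax - cx) + (cx - bx) * (ay - cy)
        if abs(det) < 1e-16:
            continue  # vertically degenerate face
        w1 = ((by - cy) * (px - cx) + (cx - bx) * (py - cy)) / det
        w2 = ((cy - ay) * (px - cx) + (ax - cx) * (py - cy)) / det
        w3 = 1.0 - w1 - w2
        inside = (w1 >= -eps) & (w2 >= -eps) & (w3 >= -eps)
        if not inside.any():
            continue
        z = w1[inside] * az + w2[inside] * bz + w3[inside] * cz
        cur = heights[inside]
        heights[inside] = np.where(np.isnan(cur), z, np.maximum(cur, z))
    heights = heights.reshape(ny, nx)
    if np.isnan(heights).all():
        raise ValueError("no vertical ray hit the mesh")
    if np.isnan(heights).any():
        jj, ii = np.mgrid[0:ny, 0:nx]
        good = ~np.isnan(heights)
        from scipy.interpolate import NearestNDInterpolator

        fill = NearestNDInterpolator(
            np.column_stack([ii[good], jj[good]]), heights[good]
        )
        heights[~good] = fill(ii[~good], jj[~good])
    return HeightField(heights, spacing)


def principal_curvatures(h: HeightField) -> PrincipalCurvatures:
    """Principal curvatures of the graph surface z = f(x, y).

    First/second fundamental forms from finite differences; eigenvalues of
    the shape operator, negated so convex-toward-viewer is positive, ordered
    k1 >= k2.  The one-cell border is masked.
    """
    z = h.heights
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("grid must be at least 3x3")
    d = h.spacing
    fy, fx = np.gradient(z, d, d)
    fyy, fyx = np.gradient(fy, d, d)
    _, fxx_ = np.gradient(fx, d, d)
    fxx = fxx_
    fxy = fyx
    fyy = fyy

    w2 = 1.0 + fx**2 + fy**2
    w = np.sqrt(w2)
    # fundamental forms (upward normal)
    E, F, G = 1.0 + fx**2, fx * fy, 1.0 + fy**2
    L, M, N = fxx / w, fxy / w, fyy / w
    # shape operator S = I^-1 II; eigenvalues via mean/Gaussian curvature
    H = (E * N - 2.0 * F * M + G * L) / (2.0 * (E * G - F**2))
    K = (L * N - M**2) / (E * G - F**2)
    disc = np.maximum(H**2 - K, 0.0)
    root = np.sqrt(disc)
    ka, kb = H + root, H - root
    # convex-outward positive: negate the upward-normal curvatures
    k1 = -kb
    k2 = -ka
    mask = np.zeros(z.shape, dtype=bool)
    mask[1:-1, 1:-1] = True
    return PrincipalCurvatures(k1, k2, mask)


def shape_index(c: PrincipalCurvatures) -> ShapeIndexMap:
    """Koenderink shape index s = -(2/pi) atan2(k1+k2, k1-k2) in [-1, 1].

    Cells with k1 = k2 = 0 (planar) have no defined shape and are masked.
    """
    k1, k2 = c.k1, c.k2
    if np.any(k1[c.mask] < k2[c.mask] - 1e-12):
        raise ValueError("k1 < k2: violates the ordering contract")
    planar = (k1 == 0) & (k2 == 0)
    s = np.where(planar, 0.0, -(2.0 / np.pi) * np.arctan2(k1 + k2, k1 - k2))
    return ShapeIndexMap(s, c.mask & ~planar)


def classify_region(si: ShapeIndexMap) -> RegionClassMap:
    """Qualitative region classes (convex / saddle / concave) + gray codes."""
    s = si.s
    classes = np.zeros(s.shape, dtype=np.int8)
    classes[s <= -REGION_THRESHOLD] = CONVEX
    classes[s >= REGION_THRESHOLD] = CONCAVE
    gray = (1.0 - s) / 2.0
    return RegionClassMap(classes, gray, si.mask)


def write_heightfield_table(h: HeightField, path) -> None:
    """Flat (x index, y index, value) table, tab-separated."""
    ny, nx = h.heights.shape
    jj, ii = np.mgrid[0:ny, 0:nx]
    arr = np.column_stack([ii.ravel(), jj.ravel(), h.heights.ravel()])
    np.savetxt(path, arr, fmt=["%d", "%d", "%.9g"], delimiter="\t",
               header="x_index\ty_index\tvalue")


def write_grayscale_png(values: np.ndarray, path) -> None:
    """8-bit grayscale preview, min-max scaled."""
    import imageio.v3 as iio

    v = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(v), np.nanmax(v)
    scaled = np.zeros_like(v) if hi <= lo else (v - lo) / (hi - lo)
    iio.imwrite(path, np.round(255 * np.nan_to_num(scaled)).astype(np.uint8))
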