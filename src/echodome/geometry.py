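"""Dome targets, triangle meshes and voxel occupancy grids.

The discrimination targets are half-ellipsoid shells ("domes") with
front/back entry holes at floor level, modelled after the paper roosts that
Pipistrellus abramus uses in captivity.  Five variants are distinguished:

* ``FULL`` (T1)               -- the trained operant stimulus, rough surface
* ``BACK_HALF_REMOVED`` (T2)  -- everything behind the transverse midplane cut away
* ``BACK_HOLE_PLUGGED`` (T3)  -- the rear hole filled flush
* ``SMOOTH`` (T4)             -- same shape as T1 with zero surface roughness
* ``FRONT_HOLE_PLUGGED`` (T5) -- the front hole filled flush

All lengths are millimetres.  The dome's local frame has its origin at the
centre of the base ellipse, ``x`` along the long (walking) axis with the
front face at ``+x``, and ``z`` up.
"""

from __future__ import annotations

import enum
import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.ndimage import gaussian_filter
from skimage.measure import marching_cubes


class GeometryError(ValueError):
    """A target specification violates one of its constraints."""


class STLParseError(ValueError):
    """An STL file could not be parsed as a triangle mesh."""


class DomeVariant(enum.Enum):
    FULL = "T1"
    BACK_HALF_REMOVED = "T2"
    BACK_HOLE_PLUGGED = "T3"
    SMOOTH = "T4"
    FRONT_HOLE_PLUGGED = "T5"

    @classmethod
    def from_label(cls, label: "str | DomeVariant") -> "DomeVariant":
        if isinstance(label, cls):
            return label
        for v in cls:
            if label in (v.name, v.value):
                return v
        raise GeometryError(f"unknown dome variant {label!r}")


@dataclass(frozen=True)
class DomeSpec:
    """Parametric description of one discrimination target.

    Defaults reproduce the printed envelope (146 x 98 x 54 mm) and the
    Rz = 3.3 mm surface roughness of the rough variants.  Hole diameter and
    wall thickness are not reported for the physical targets; the defaults
    (30 mm holes centred on the long axis at floor level, 3 mm walls) are
    explicit stand-in choices and are configurable.
    """

    outer_length: float = 146.0
    outer_width: float = 98.0
    outer_height: float = 54.0
    wall_thickness: float = 3.0
    front_hole_diameter: float = 30.0
    back_hole_diameter: float = 30.0
    roughness_rz: float = 3.3
    variant: DomeVariant = DomeVariant.FULL
    roughness_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", DomeVariant.from_label(self.variant))
        dims = (self.outer_length, self.outer_width, self.outer_height)
        if min(dims) <= 0:
            raise GeometryError(f"outer dimensions must be positive, got {dims}")
        if not 0 < self.wall_thickness < min(dims) / 2:
            raise GeometryError(
                f"wall_thickness must lie in (0, {min(dims) / 2}), got {self.wall_thickness}"
            )
        for name in ("front_hole_diameter", "back_hole_diameter"):
            d = getattr(self, name)
            if not 0 <= d < self.outer_width:
                raise GeometryError(f"{name} must lie in [0, outer_width), got {d}")
        if self.roughness_rz < 0:
            raise GeometryError(f"roughness_rz must be >= 0, got {self.roughness_rz}")
        if self.variant is DomeVariant.SMOOTH:
            object.__setattr__(self, "roughness_rz", 0.0)
        # the roughness field is centred on the surface, so the inward
        # excursion is rz/2; the shell self-intersects when that reaches the
        # inner surface
        if self.roughness_rz / 2 >= self.wall_thickness:
            raise GeometryError(
                "roughness_rz/2 must be smaller than wall_thickness "
                f"({self.roughness_rz}/2 >= {self.wall_thickness}): shell would self-intersect"
            )

    @property
    def target_id(self) -> str:
        return self.variant.value

    def with_variant(self, variant: "str | DomeVariant") -> "DomeSpec":
        v = DomeVariant.from_label(variant)
        rz = 0.0 if v is DomeVariant.SMOOTH else self.roughness_rz
        return replace(self, variant=v, roughness_rz=rz)


@dataclass
class TriMesh:
    """Indexed triangle mesh (vertices in mm)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise GeometryError("face index out of range")
        if len(self.faces) and self.faces.min() < 0:
            raise GeometryError("negative face index")

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) array of [min, max] corner coordinates."""
        return np.array([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    @property
    def extents(self) -> np.ndarray:
        b = self.bounds
        return b[1] - b[0]

    def volume(self) -> float:
        """Enclosed volume (mm^3) by the divergence theorem; assumes closed mesh."""
        v = self.vertices
        t = v[self.faces]
        return float(abs(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum()) / 6.0)

    def translated(self, offset) -> "TriMesh":
        return TriMesh(self.vertices + np.asarray(offset, dtype=float), self.faces.copy())

    def as_trimesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


@dataclass
class VoxelGrid:
    """Boolean occupancy lattice registered to a coordinate frame.

    ``occupancy[i, j, k]`` covers the cube whose centre is
    ``origin + (i + 0.5, j + 0.5, k + 0.5) * dx``.
    """

    occupancy: np.ndarray
    dx: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 3:
            raise GeometryError("occupancy must be a 3D array")
        if self.dx <= 0:
            raise GeometryError(f"dx must be positive, got {self.dx}")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def count(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume(self) -> float:
        """Occupied volume in mm^3."""
        return self.count * self.dx**3


# ---------------------------------------------------------------------------
# implicit dome model
#
# The dome shell is a half super-ellipsoid: quadratic in the vertical
# direction but with exponent 4 in the horizontal plane, which gives the
# blunt, roost-like front face of the physical paper domes.  A purely
# quadratic ellipsoid would taper to a point at floor level exactly where
# the entry arch is cut, and the cut would then shorten the printed
# 146 mm envelope by several millimetres.

_HORIZ_EXP = 4.0


def _super_radius(x, y, z, ax, by, cz):
    """Generalised radius of the half super-ellipsoid (1 on the surface)."""
    horiz = (np.abs(x) / ax) ** _HORIZ_EXP + (np.abs(y) / by) ** _HORIZ_EXP
    return np.sqrt(horiz ** (2.0 / _HORIZ_EXP) + (z / cz) ** 2)


def _dome_field(spec: DomeSpec, pts: np.ndarray) -> np.ndarray:
    """Approximate signed distance of the dome solid; negative inside.

    CSG combination of the shell surfaces, the base half-space and the hole
    cylinders.  The pseudo-distances are exact enough for sub-voxel root
    finding by marching cubes.
    """
    a, b, c = spec.outer_length / 2, spec.outer_width / 2, spec.outer_height
    t = spec.wall_thickness
    x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]

    def surface(ax, by, cz):
        return (_super_radius(x, y, z, ax, by, cz) - 1.0) * min(ax, by, cz)

    s = np.maximum(surface(a, b, c), -surface(a - t, b - t, c - t))
    s = np.maximum(s, -z)  # keep z >= 0

    rho = np.sqrt(y**2 + z**2)
    holes = []
    if spec.variant is not DomeVariant.FRONT_HOLE_PLUGGED and spec.front_hole_diameter > 0:
        holes.append(np.maximum(rho - spec.front_hole_diameter / 2, -x))
    if (
        spec.variant not in (DomeVariant.BACK_HOLE_PLUGGED, DomeVariant.BACK_HALF_REMOVED)
        and spec.back_hole_diameter > 0
    ):
        holes.append(np.maximum(rho - spec.back_hole_diameter / 2, x))
    for h in holes:
        s = np.maximum(s, -h)
    if spec.variant is DomeVariant.BACK_HALF_REMOVED:
        s = np.maximum(s, -x)  # keep the front half only
    return s


def _outer_surface_info(spec: DomeSpec, verts: np.ndarray, tol: float):
    """Mask of vertices on the outer shell surface plus outward normals."""
    a, b, c = spec.outer_length / 2, spec.outer_width / 2, spec.outer_height
    x, y, z = verts[:, 0], verts[:, 1], verts[:, 2]
    r = _super_radius(x, y, z, a, b, c)
    mask = (np.abs(r - 1.0) * min(a, b, c) < tol) & (z > tol)
    # outward normal by finite differences of the radius function
    h = 1e-3
    grad = np.stack(
        [
            _super_radius(x + h, y, z, a, b, c) - _super_radius(x - h, y, z, a, b, c),
            _super_radius(x, y + h, z, a, b, c) - _super_radius(x, y - h, z, a, b, c),
            _super_radius(x, y, z + h, a, b, c) - _super_radius(x, y, z - h, a, b, c),
        ],
        axis=1,
    )
    norm = np.linalg.norm(grad, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return mask, grad / norm


def _canonical_surface_points(spec: DomeSpec, n_u: int = 160, n_v: int = 80) -> np.ndarray:
    """Variant-independent sample of the outer surface.

    Used as the reference set when rescaling the roughness field so that all
    variants of the same base spec receive the identical displacement field
    (edits stay local to the edited regions).
    """
    a, b, c = spec.outer_length / 2, spec.outer_width / 2, spec.outer_height
    u = np.linspace(0, 2 * np.pi, n_u, endpoint=False)
    v = np.linspace(1e-3, np.pi / 2 - 1e-3, n_v)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    # parametrise the super-ellipse cross-section at each height
    cz = np.cos(vv)
    horiz = np.sin(vv)
    cu, su = np.cos(uu), np.sin(uu)
    e = 2.0 / _HORIZ_EXP
    x = a * np.sign(cu) * np.abs(cu) ** e * horiz
    y = b * np.sign(su) * np.abs(su) ** e * horiz
    z = c * cz
    return np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)


def make_dome(spec: DomeSpec, mesh_resolution: float = 0.5) -> TriMesh:
    """Build the dome variant as a watertight triangle mesh.

    The shell is extracted from the implicit solid by marching cubes at
    ``mesh_resolution`` (mm), then surface roughness is applied to the outer
    ellipsoid vertices (see :func:`apply_roughness`).  For the
    ``BACK_HALF_REMOVED`` variant the midplane cut is closed by the cut
    cross-section, which leaves the occupied solid unchanged.
    """
    a, b = spec.outer_length / 2, spec.outer_width / 2
    h = mesh_resolution
    pad = 2 * h
    lo = np.array([-a - pad, -b - pad, -pad])
    hi = np.array([a + pad, b + pad, spec.outer_height + pad])
    shape = np.ceil((hi - lo) / h).astype(int) + 1
    grid = np.stack(
        np.meshgrid(
            lo[0] + np.arange(shape[0]) * h,
            lo[1] + np.arange(shape[1]) * h,
            lo[2] + np.arange(shape[2]) * h,
            indexing="ij",
        ),
        axis=-1,
    )
    fieldv = _dome_field(spec, grid)
    verts, faces, _, _ = marching_cubes(fieldv, level=0.0, spacing=(h, h, h))
    verts = verts + lo
    mesh = TriMesh(verts, faces)
    if spec.roughness_rz > 0:
        mask, normals = _outer_surface_info(spec, mesh.vertices, tol=0.6 * h)
        mesh = apply_roughness(
            mesh,
            spec.roughness_rz,
            spec.roughness_seed,
            vertex_mask=mask,
            normals=normals,
            wall_thickness=spec.wall_thickness,
            reference_points=_canonical_surface_points(spec),
        )
    return mesh


def _roughness_field(seed: int, correlation_length: float, n_modes: int = 256):
    """Seeded band-limited random field as a function of 3D position.

    Random-phase spectral synthesis: a sum of cosines whose wavevectors are
    drawn from an isotropic Gaussian of scale 1/correlation_length (the
    squared-exponential spectrum).  The returned callable is a deterministic
    function of position, so meshes with different bounding boxes sample the
    *same* field -- variant edits stay local.
    """
    rng = np.random.default_rng(seed)
    k = rng.standard_normal((n_modes, 3)) / correlation_length
    phi = rng.uniform(0, 2 * np.pi, n_modes)

    def field(points: np.ndarray) -> np.ndarray:
        return np.cos(points @ k.T + phi).sum(axis=1) * np.sqrt(2.0 / n_modes)

    return field


def apply_roughness(
    mesh: TriMesh,
    rz: float,
    seed: int,
    vertex_mask: np.ndarray | None = None,
    normals: np.ndarray | None = None,
    correlation_length: float = 8.0,
    wall_thickness: float | None = None,
    reference_points: np.ndarray | None = None,
) -> TriMesh:
    """Displace surface vertices by a seeded band-limited random field.

    The field (correlation length in mm) is rescaled so that its
    peak-to-valley height over ``reference_points`` (default: the selected
    vertices themselves) equals ``rz``; displacement is along ``normals``
    (default: area-weighted vertex normals) and restricted to
    ``vertex_mask`` (e.g. the outer shell surface).
    """
    if rz < 0:
        raise GeometryError(f"rz must be >= 0, got {rz}")
    if rz == 0:
        return TriMesh(mesh.vertices.copy(), mesh.faces.copy())
    if wall_thickness is not None and rz / 2 >= wall_thickness:
        raise GeometryError(
            f"rz/2 = {rz / 2} >= wall thickness {wall_thickness}: shell would self-intersect"
        )
    verts = mesh.vertices.copy()
    if vertex_mask is None:
        vertex_mask = np.ones(len(verts), dtype=bool)
    if normals is None:
        normals = mesh.as_trimesh().vertex_normals.copy()

    field = _roughness_field(seed, correlation_length)
    ref = verts[vertex_mask] if reference_points is None else reference_points
    ref_vals = field(ref)
    span = ref_vals.max() - ref_vals.min()
    if span == 0:
        return TriMesh(verts, mesh.faces.copy())
    centre = (ref_vals.max() + ref_vals.min()) / 2.0
    disp = (field(verts[vertex_mask]) - centre) * (rz / span)
    verts[vertex_mask] += disp[:, None] * np.asarray(normals)[vertex_mask]
    return TriMesh(verts, mesh.faces.copy())


# ---------------------------------------------------------------------------
# voxelization


@njit(cache=True)
def _column_crossings(verts, faces, origin, dx, nx, ny, max_per_col):  # pragma: no cover
    counts = np.zeros((nx, ny), dtype=np.int32)
    zs = np.full((nx, ny, max_per_col), np.nan)
    # tiny deterministic offset avoids rays passing exactly through edges
    ex = 1e-7 * dx
    ey = 2e-7 * dx
    for f in range(faces.shape[0]):
        ia, ib, ic = faces[f, 0], faces[f, 1], faces[f, 2]
        ax, ay, az = verts[ia, 0], verts[ia, 1], verts[ia, 2]
        bx, by, bz = verts[ib, 0], verts[ib, 1], verts[ib, 2]
        cx, cy, cz = verts[ic, 0], verts[ic, 1], verts[ic, 2]
        xmin = min(ax, bx, cx)
        xmax = max(ax, bx, cx)
        ymin = min(ay, by, cy)
        ymax = max(ay, by, cy)
        i0 = max(0, int(np.ceil((xmin - origin[0] - ex) / dx - 0.5)))
        i1 = min(nx - 1, int(np.floor((xmax - origin[0] - ex) / dx - 0.5)))
        j0 = max(0, int(np.ceil((ymin - origin[1] - ey) / dx - 0.5)))
        j1 = min(ny - 1, int(np.floor((ymax - origin[1] - ey) / dx - 0.5)))
        if i1 < i0 or j1 < j0:
            continue
        d00x = bx - ax
        d00y = by - ay
        d01x = cx - ax
        d01y = cy - ay
        det = d00x * d01y - d01x * d00y
        if det == 0.0:
            continue  # degenerate in projection: vertical triangle, no z crossing
        inv = 1.0 / det
        for i in range(i0, i1 + 1):
            px = origin[0] + (i + 0.5) * dx + ex - ax
            for j in range(j0, j1 + 1):
                py = origin[1] + (j + 0.5) * dx + ey - ay
                u = (px * d01y - d01x * py) * inv
                v = (d00x * py - px * d00y) * inv
                if u < 0.0 or v < 0.0 or u + v > 1.0:
                    continue
                zc = az + u * (bz - az) + v * (cz - az)
                n = counts[i, j]
                if n < max_per_col:
                    zs[i, j, n] = zc
                counts[i, j] = n + 1
    return counts, zs


@njit(cache=True)
def _fill_columns(counts, zs, origin_z, dx, nz, occ):  # pragma: no cover
    nx, ny = counts.shape
    for i in range(nx):
        for j in range(ny):
            n = counts[i, j]
            if n < 2:
                continue
            col = np.sort(zs[i, j, :n])
            m = (n // 2) * 2  # drop an unmatched crossing, if any
            for p in range(0, m, 2):
                zlo, zhi = col[p], col[p + 1]
                k0 = max(0, int(np.ceil((zlo - origin_z) / dx - 0.5)))
                k1 = min(nz - 1, int(np.floor((zhi - origin_z) / dx - 0.5)))
                for k in range(k0, k1 + 1):
                    occ[i, j, k] = True


def voxelize(
    mesh: TriMesh,
    dx: float,
    origin: np.ndarray | None = None,
    shape: tuple[int, int, int] | None = None,
) -> VoxelGrid:
    """Occupancy grid of a closed mesh: a voxel is occupied iff its centre
    lies inside the solid (column parity ray casting along ``z``).

    ``origin``/``shape`` register the grid to an external frame (e.g. the
    simulation lattice); by default the grid covers the mesh bounding box.
    """
    if dx <= 0:
        raise GeometryError(f"dx must be positive, got {dx}")
    if len(mesh.faces) == 0:
        raise GeometryError("cannot voxelize an empty mesh")
    b = mesh.bounds
    if origin is None:
        # centres start half a cell inside the bounding box, so an
        # axis-aligned solid with integral extents is sampled exactly
        origin = b[0].copy()
    origin = np.asarray(origin, dtype=float)
    if shape is None:
        shape = tuple(np.maximum(np.ceil((b[1] - origin) / dx).astype(int), 1))
    nx, ny, nz = shape
    # generous bound on crossings per column: shells cross a column a few times
    max_per_col = 64
    counts, zs = _column_crossings(
        np.ascontiguousarray(mesh.vertices),
        np.ascontiguousarray(mesh.faces),
        origin,
        float(dx),
        nx,
        ny,
        max_per_col,
    )
    if counts.max() > max_per_col:
        raise GeometryError("mesh produced too many ray crossings per column")
    occ = np.zeros((nx, ny, nz), dtype=np.bool_)
    _fill_columns(counts, zs, origin[2], float(dx), nz, occ)
    if occ.sum() == 0:
        raise GeometryError(
            "voxelization produced no occupied voxels; mesh may be open or dx too coarse"
        )
    return VoxelGrid(occ, dx, origin)


# ---------------------------------------------------------------------------
# STL interchange


def write_stl(mesh: TriMesh, path, binary: bool = True) -> None:
    """Write a mesh as binary (default) or ASCII STL."""
    tm = mesh.as_trimesh()
    file_type = "stl" if binary else "stl_ascii"
    tm.export(str(path), file_type=file_type)


def read_stl(path) -> TriMesh:
    """Read a binary or ASCII STL file, merging duplicate vertices."""
    import trimesh

    try:
        tm = trimesh.load_mesh(str(path), file_type="stl")
    except Exception as exc:  # malformed header, truncated body, ...
        raise STLParseError(f"could not parse STL file {path}: {exc}") from exc
    if tm.is_empty or len(tm.faces) == 0:
        raise STLParseError(f"STL file {path} contains no triangles")
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def mesh_digest(mesh: TriMesh) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(mesh.vertices).tobytes())
    h.update(np.ascontiguousarray(mesh.faces).tobytes())
    return h.hexdigest()[:16]
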