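"""3D wave-equation FDTD (WE-FDTD) solver.

The scalar wave equation is discretised directly (no particle-velocity
fields): a second-order leapfrog update on the 7-point Laplacian stencil,

    p(n+1) = 2 p(n) - p(n-1) + chi^2 * L7[p(n)],      chi = c dt / dx.

Boundaries:

* obstacle voxels are rigid (zero normal derivative, mirror ghost);
* the floor is a solid slab whose surface is a locally reacting impedance
  boundary tuned to a prescribed normal-incidence pressure reflection
  coefficient R, via the semi-implicit ghost condition
  ``p_ghost - p = -(chi / 2 zeta) (p(n+1) - p(n-1))`` with
  ``zeta = (1 + R) / (1 - R)``;
* the remaining outer faces carry a convolutional perfectly matched layer
  (recursive memory variables on collocated first and second spatial
  derivatives, quadratic damping profile).

Interface units are mm / ms (matching how the experiments are described);
times inside traces are seconds.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass

import numpy as np
from numba import njit, prange

from .geometry import VoxelGrid

_CFL_3D_BOUND = 1.0 / math.sqrt(3.0)

AIR, RIGID, FLOOR = 0, 1, 2


class StabilityError(ValueError):
    """Configuration violates the explicit-scheme stability bound."""

class ConfigurationError(ValueError):
    """Simulation configuration is inconsistent."""

class DivergenceError(RuntimeError):
    """The field blew up (instability or bad input)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Description of one WE-FDTD run.

    Defaults reproduce the reference echo-simulation conditions: a
    420 x 220 x 80 mm space, speed of sound 340 m/s, Courant number 0.5,
    2.65 ms of simulated time, a 10 mm floor slab with reflection
    coefficient 0.99, and source/receiver 14 / 17 mm above the floor.
    ``dx`` defaults to 1 mm; production-scale runs use 0.2 mm.
    """

    domain_size: tuple[float, float, float] = (420.0, 220.0, 80.0)
    dx: float = 1.0
    cfl: float = 0.5
    c: float = 340.0
    duration_ms: float = 2.65
    pml_cells: int = 10
    pml_profile_order: int = 2
    pml_max_damping: float | None = None  # 1/s; None -> graded-layer rule
    pml_target_reflection: float = 1e-4
    pml_faces: tuple[str, ...] = ("x-", "x+", "y-", "y+", "z+")
    floor_thickness: float = 10.0
    floor_reflection: float = 0.99
    source_position: tuple[float, float, float] = (380.0, 110.0, 24.0)
    receiver_position: tuple[float, float, float] = (380.0, 110.0, 27.0)
    precision: str = "float32"

    def __post_init__(self) -> None:
        if self.cfl <= 0:
            raise StabilityError(f"Courant number must be positive, got {self.cfl}")
        if self.cfl > _CFL_3D_BOUND + 1e-12:
            raise StabilityError(
                f"Courant number {self.cfl} exceeds the 3D stability bound "
                f"1/sqrt(3) = {_CFL_3D_BOUND:.6f}"
            )
        if self.dx <= 0:
            raise ConfigurationError(f"dx must be positive, got {self.dx}")
        for L in self.domain_size:
            n = L / self.dx
            if abs(n - round(n)) > 1e-6:
                raise ConfigurationError(
                    f"dx = {self.dx} does not divide domain dimension {L} evenly"
                )
        if self.duration_ms <= 0:
            raise ConfigurationError(f"duration must be positive, got {self.duration_ms}")
        if not 0.0 <= self.floor_reflection <= 1.0:
            raise ConfigurationError(
                f"floor_reflection must lie in [0, 1], got {self.floor_reflection}"
            )
        if self.floor_thickness < 0:
            raise ConfigurationError("floor_thickness must be >= 0")
        bad = set(self.pml_faces) - {"x-", "x+", "y-", "y+", "z-", "z+"}
        if bad:
            raise ConfigurationError(f"unknown PML faces {sorted(bad)}")
        if self.pml_faces:
            if self.pml_cells < 4:
                raise ConfigurationError(f"pml_cells must be >= 4, got {self.pml_cells}")
            shape = self.grid_shape
            for axis, faces in enumerate((("x-", "x+"), ("y-", "y+"), ("z-", "z+"))):
                if any(f in self.pml_faces for f in faces):
                    if self.pml_cells >= shape[axis] // 2:
                        raise ConfigurationError(
                            f"pml_cells = {self.pml_cells} is >= half the grid size "
                            f"along axis {axis}"
                        )
        if self.precision not in ("float32", "float64"):
            raise ConfigurationError(f"precision must be float32 or float64")
        for name in ("source_position", "receiver_position"):
            self._check_point(getattr(self, name), name)

    def _check_point(self, pos, name: str) -> None:
        pos = np.asarray(pos, dtype=float)
        lo = np.zeros(3)
        hi = np.asarray(self.domain_size, dtype=float)
        if np.any(pos <= lo) or np.any(pos >= hi):
            raise ConfigurationError(f"{name} {tuple(pos)} is outside the domain {tuple(hi)}")
        if pos[2] <= self.floor_thickness:
            raise ConfigurationError(f"{name} lies inside the floor slab")
        pml = self.pml_cells * self.dx
        for axis, (mface, pface) in enumerate([("x-", "x+"), ("y-", "y+"), ("z-", "z+")]):
            if mface in self.pml_faces and pos[axis] < pml:
                raise ConfigurationError(f"{name} lies inside the {mface} PML layer")
            if pface in self.pml_faces and pos[axis] > hi[axis] - pml:
                raise ConfigurationError(f"{name} lies inside the {pface} PML layer")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(int(round(L / self.dx)) for L in self.domain_size)

    @property
    def dt(self) -> float:
        """Time step in seconds: dt = chi * dx / c."""
        return self.cfl * (self.dx * 1e-3) / self.c

    @property
    def n_steps(self) -> int:
        return int(math.floor(self.duration_ms * 1e-3 / self.dt))

    def cell_index(self, pos) -> tuple[int, int, int]:
        idx = tuple(int(round(p / self.dx - 0.5)) for p in pos)
        shape = self.grid_shape
        return tuple(min(max(i, 0), n - 1) for i, n in zip(idx, shape))

    def digest(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:16]


def compute_time_step(config: SimulationConfig) -> float:
    """Solver time step dt = chi * dx / c, in seconds."""
    return config.dt


@dataclass
class PMLCoefficients:
    """Per-axis damping profiles sigma(i) in 1/s (zero in the interior)."""

    sigma_x: np.ndarray
    sigma_y: np.ndarray
    sigma_z: np.ndarray
    sigma_max: float

    def recursion_coefficients(self, dt: float, dtype):
        """(b, a) arrays of the recursive memory-variable update per axis."""
        out = []
        for s in (self.sigma_x, self.sigma_y, self.sigma_z):
            b = np.exp(-s * dt).astype(dtype)
            a = (b - 1.0).astype(dtype)
            out.append((b, a))
        return out


def apply_pml_coefficients(config: SimulationConfig) -> PMLCoefficients:
    """Polynomial-graded damping profiles for the configured PML faces.

    sigma rises from zero at the layer entrance to ``pml_max_damping`` at the
    outermost cell with the configured profile order.  The default maximum
    follows the graded-layer rule sigma_max = -(m+1) c ln(R0) / (2 L) with
    target reflection R0 = ``pml_target_reflection``.
    """
    n = config.pml_cells
    L = n * config.dx * 1e-3
    if config.pml_max_damping is not None:
        smax = config.pml_max_damping
    else:
        smax = (
            -(config.pml_profile_order + 1)
            * config.c
            * math.log(config.pml_target_reflection)
            / (2.0 * L)
        )
    shape = config.grid_shape
    profiles = []
    for axis, (mface, pface) in enumerate([("x-", "x+"), ("y-", "y+"), ("z-", "z+")]):
        sig = np.zeros(shape[axis])
        ramp = smax * (np.arange(1, n + 1) / n) ** config.pml_profile_order
        if mface in config.pml_faces:
            sig[:n] = ramp[::-1]
        if pface in config.pml_faces:
            sig[-n:] = ramp
        profiles.append(sig)
    return PMLCoefficients(*profiles, sigma_max=smax)


@dataclass
class FloorBoundary:
    """Impedance treatment of the floor slab surface."""

    reflection: float
    zeta: float  # normalised specific impedance (inf for rigid)
    slab_cells: int

    @property
    def ghost_coefficient(self) -> float:
        """kappa such that each floor-adjacent face contributes
        (chi * kappa / 2) * (p(n+1) - p(n-1)) to the ghost value."""
        return 0.0 if math.isinf(self.zeta) else 1.0 / self.zeta


def floor_boundary(config: SimulationConfig) -> FloorBoundary:
    R = config.floor_reflection
    zeta = math.inf if R >= 1.0 else (1.0 + R) / (1.0 - R)
    return FloorBoundary(R, zeta, int(round(config.floor_thickness / config.dx)))


@dataclass
class ReceiverTrace:
    """Pressure recorded at the receiver, one sample per solver step."""

    samples: np.ndarray
    dt: float
    config_digest: str = ""
    source_position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    receiver_position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    energies: np.ndarray | None = None

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(len(self.samples)) * self.dt


# ---------------------------------------------------------------------------
# kernels


@njit(parallel=True, fastmath=True, cache=True)
def _update_psi(
    p1, psix, psiy, psiz, bx, ax, by, ay, bz, az, mask,
    ix0, ix1, jx0, jx1, kx0, kx1,
):  # pragma: no cover
    """Recursive memory-variable update, restricted to the PML slabs.

    (ix0, ix1) etc. are half-open [lo, hi) bounds of the low slab; the high
    slab is the mirror at the far end.  A bound pair (0, 0) disables that
    side.  psi stays identically zero outside the slabs, so skipping the
    interior is exact.
    """
    nx, ny, nz = p1.shape
    # x-direction slabs
    for i in prange(nx):
        if not ((ix0 <= i < ix1) or (nx - ix1 <= i < nx - ix0)):
            continue
        axi = ax[i]
        bxi = bx[i]
        if axi == 0.0:
            continue
        for j in range(ny):
            for k in range(nz):
                if mask[i, j, k] != AIR:
                    continue
                c = p1[i, j, k]
                pm = p1[i - 1, j, k] if i > 0 and mask[i - 1, j, k] == AIR else c
                pp = p1[i + 1, j, k] if i < nx - 1 and mask[i + 1, j, k] == AIR else c
                psix[i, j, k] = bxi * psix[i, j, k] + axi * 0.5 * (pp - pm)
    # y-direction slabs
    for i in prange(nx):
        for j in range(ny):
            if not ((jx0 <= j < jx1) or (ny - jx1 <= j < ny - jx0)):
                continue
            ayj = ay[j]
            byj = by[j]
            if ayj == 0.0:
                continue
            for k in range(nz):
                if mask[i, j, k] != AIR:
                    continue
                c = p1[i, j, k]
                pm = p1[i, j - 1, k] if j > 0 and mask[i, j - 1, k] == AIR else c
                pp = p1[i, j + 1, k] if j < ny - 1 and mask[i, j + 1, k] == AIR else c
                psiy[i, j, k] = byj * psiy[i, j, k] + ayj * 0.5 * (pp - pm)
    # z-direction slabs
    for i in prange(nx):
        for j in range(ny):
            for k0 in range(2):
                lo = kx0 if k0 == 0 else nz - kx1
                hi = kx1 if k0 == 0 else nz - kx0
                for k in range(lo, hi):
                    azk = az[k]
                    if azk == 0.0:
                        continue
                    if mask[i, j, k] != AIR:
                        continue
                    c = p1[i, j, k]
                    pm = p1[i, j, k - 1] if k > 0 and mask[i, j, k - 1] == AIR else c
                    pp = p1[i, j, k + 1] if k < nz - 1 and mask[i, j, k + 1] == AIR else c
                    psiz[i, j, k] = bz[k] * psiz[i, j, k] + azk * 0.5 * (pp - pm)


@njit(inline="always")
def _cell(
    p0, p1, p2, psix, psiy, psiz, xix, xiy, xiz, bx, ax, by, ay, bz, az,
    mask, chi2, fcoef, i, j, k,
):  # pragma: no cover
    """General single-cell update: boundary mirrors, floor impedance, CPML."""
    nx, ny, nz = p1.shape
    if mask[i, j, k] != AIR:
        p2[i, j, k] = 0.0
        return
    axi = ax[i]
    ayj = ay[j]
    azk = az[k]
    c = p1[i, j, k]
    m = 0
    # --- x axis
    lx = c * 0  # typed zero
    if i > 0:
        mm = mask[i - 1, j, k]
        if mm == AIR:
            lx += p1[i - 1, j, k] - c
        elif mm == FLOOR:
            m += 1
    if i < nx - 1:
        mm = mask[i + 1, j, k]
        if mm == AIR:
            lx += p1[i + 1, j, k] - c
        elif mm == FLOOR:
            m += 1
    if axi != 0.0:
        psm = psix[i - 1, j, k] if i > 0 else psix[i, j, k] * 0
        psp = psix[i + 1, j, k] if i < nx - 1 else psix[i, j, k] * 0
        l2 = lx + 0.5 * (psp - psm)
        xi = bx[i] * xix[i, j, k] + axi * l2
        xix[i, j, k] = xi
        lx = l2 + xi
    # --- y axis
    ly = c * 0
    if j > 0:
        mm = mask[i, j - 1, k]
        if mm == AIR:
            ly += p1[i, j - 1, k] - c
        elif mm == FLOOR:
            m += 1
    if j < ny - 1:
        mm = mask[i, j + 1, k]
        if mm == AIR:
            ly += p1[i, j + 1, k] - c
        elif mm == FLOOR:
            m += 1
    if ayj != 0.0:
        psm = psiy[i, j - 1, k] if j > 0 else psiy[i, j, k] * 0
        psp = psiy[i, j + 1, k] if j < ny - 1 else psiy[i, j, k] * 0
        l2 = ly + 0.5 * (psp - psm)
        xi = by[j] * xiy[i, j, k] + ayj * l2
        xiy[i, j, k] = xi
        ly = l2 + xi
    # --- z axis
    lz = c * 0
    if k > 0:
        mm = mask[i, j, k - 1]
        if mm == AIR:
            lz += p1[i, j, k - 1] - c
        elif mm == FLOOR:
            m += 1
    if k < nz - 1:
        mm = mask[i, j, k + 1]
        if mm == AIR:
            lz += p1[i, j, k + 1] - c
        elif mm == FLOOR:
            m += 1
    if azk != 0.0:
        psm = psiz[i, j, k - 1] if k > 0 else psiz[i, j, k] * 0
        psp = psiz[i, j, k + 1] if k < nz - 1 else psiz[i, j, k] * 0
        l2 = lz + 0.5 * (psp - psm)
        xi = bz[k] * xiz[i, j, k] + azk * l2
        xiz[i, j, k] = xi
        lz = l2 + xi
    if m == 0:
        p2[i, j, k] = 2.0 * c - p0[i, j, k] + chi2 * (lx + ly + lz)
    else:
        fc = fcoef * m
        p2[i, j, k] = (
            2.0 * c - (1.0 - fc) * p0[i, j, k] + chi2 * (lx + ly + lz)
        ) / (1.0 + fc)


@njit(parallel=True, fastmath=True, cache=True)
def _update_p(
    p0, p1, p2, psix, psiy, psiz, xix, xiy, xiz, bx, ax, by, ay, bz, az,
    mask, gencol, k_lo, k_hi, chi2, fcoef,
):  # pragma: no cover
    """Leapfrog pressure update.

    Columns flagged in ``gencol`` (domain edges, PML slabs, obstacle
    neighbourhoods) and the floor/top cell ranges take the general per-cell
    path; the homogeneous interior uses a tight 7-point stencil.
    """
    nx, ny, nz = p1.shape
    for i in prange(nx):
        for j in range(ny):
            if gencol[i, j]:
                for k in range(nz):
                    _cell(
                        p0, p1, p2, psix, psiy, psiz, xix, xiy, xiz,
                        bx, ax, by, ay, bz, az, mask, chi2, fcoef, i, j, k,
                    )
            else:
                for k in range(k_lo):
                    _cell(
                        p0, p1, p2, psix, psiy, psiz, xix, xiy, xiz,
                        bx, ax, by, ay, bz, az, mask, chi2, fcoef, i, j, k,
                    )
                for k in range(k_lo, k_hi):
                    c = p1[i, j, k]
                    lap = (
                        p1[i - 1, j, k] + p1[i + 1, j, k]
                        + p1[i, j - 1, k] + p1[i, j + 1, k]
                        + p1[i, j, k - 1] + p1[i, j, k + 1]
                        - 6.0 * c
                    )
                    p2[i, j, k] = 2.0 * c - p0[i, j, k] + chi2 * lap
                for k in range(k_hi, nz):
                    _cell(
                        p0, p1, p2, psix, psiy, psiz, xix, xiy, xiz,
                        bx, ax, by, ay, bz, az, mask, chi2, fcoef, i, j, k,
                    )


def _discrete_energy(p_old, p_new, mask, c, dt, dx) -> float:
    """Conserved leapfrog energy of the air region (rigid enclosure)."""
    air = mask == AIR
    v = (p_new.astype(np.float64) - p_old) / dt
    kinetic = 0.5 * np.sum(v[air] ** 2) / c**2
    pot = 0.0
    for axis in range(3):
        d_new = np.diff(p_new.astype(np.float64), axis=axis)
        d_old = np.diff(p_old.astype(np.float64), axis=axis)
        both_air = np.logical_and(np.take(air, range(air.shape[axis] - 1), axis=axis),
                                  np.take(air, range(1, air.shape[axis]), axis=axis))
        pot += 0.5 * np.sum((d_new * d_old)[both_air]) / dx**2
    return float(kinetic + pot)


def build_mask(config: SimulationConfig, obstacles: VoxelGrid | None = None) -> np.ndarray:
    """Cell classification: air, rigid obstacle, or floor slab."""
    shape = config.grid_shape
    mask = np.zeros(shape, dtype=np.uint8)
    fb = floor_boundary(config)
    if fb.slab_cells > 0:
        mask[:, :, : fb.slab_cells] = RIGID if math.isinf(fb.zeta) else FLOOR
    if obstacles is not None:
        if abs(obstacles.dx - config.dx) > 1e-9:
            raise ConfigurationError(
                f"obstacle grid dx = {obstacles.dx} differs from solver dx = {config.dx}"
            )
        off = obstacles.origin / config.dx
        if np.any(np.abs(off - np.round(off)) > 1e-6):
            raise ConfigurationError("obstacle grid origin is not aligned to the solver lattice")
        off = np.round(off).astype(int)
        idx = np.argwhere(obstacles.occupancy) + off
        if len(idx) and (idx.min() < 0 or np.any(idx.max(axis=0) >= shape)):
            raise ConfigurationError("obstacle voxels extend outside the simulation domain")
        mask[idx[:, 0], idx[:, 1], idx[:, 2]] = RIGID
    for name in ("source_position", "receiver_position"):
        idx = config.cell_index(getattr(config, name))
        if mask[idx] != AIR:
            raise ConfigurationError(f"{name} overlaps an obstacle or the floor")
    return mask


def run_simulation(
    config: SimulationConfig,
    obstacles: VoxelGrid | None = None,
    source="impulse",
    energy_interval: int | None = None,
) -> ReceiverTrace:
    """Run the WE-FDTD scheme and record the receiver pressure every step.

    ``source`` is either ``"impulse"`` (a single-step unit excitation, the
    band-limited stand-in for an ideal impulse), ``None`` (no excitation), or
    a waveform array sampled at the solver ``dt`` added softly at the source
    node step by step.
    """
    dtype = np.float32 if config.precision == "float32" else np.float64
    mask = build_mask(config, obstacles)
    shape = config.grid_shape
    dt = config.dt
    chi = np.array(config.cfl, dtype=dtype)
    chi2 = dtype(chi * chi)

    if source is None:
        waveform = np.zeros(0, dtype=dtype)
    elif isinstance(source, str):
        if source != "impulse":
            raise ConfigurationError(f"unknown source kind {source!r}")
        waveform = np.array([1.0], dtype=dtype)
    else:
        waveform = np.asarray(source, dtype=dtype).ravel()
    amp = float(np.max(np.abs(waveform))) if len(waveform) else 0.0

    pml = apply_pml_coefficients(config)
    (bx, ax), (by, ay), (bz, az) = pml.recursion_coefficients(dt, dtype)

    fb = floor_boundary(config)
    fcoef = dtype(config.cfl / 2.0 * fb.ghost_coefficient)

    p0 = np.zeros(shape, dtype=dtype)
    p1 = np.zeros(shape, dtype=dtype)
    p2 = np.zeros(shape, dtype=dtype)
    psix = np.zeros(shape, dtype=dtype)
    psiy = np.zeros(shape, dtype=dtype)
    psiz = np.zeros(shape, dtype=dtype)
    xix = np.zeros(shape, dtype=dtype)
    xiy = np.zeros(shape, dtype=dtype)
    xiz = np.zeros(shape, dtype=dtype)

    src = config.cell_index(config.source_position)
    rcv = config.cell_index(config.receiver_position)
    n_steps = config.n_steps
    trace = np.zeros(n_steps + 1, dtype=dtype)
    energies = [] if energy_interval else None

    npml = config.pml_cells if config.pml_faces else 0
    nx, ny, nz = shape
    # columns needing the general path: domain edges, lateral PML slabs, and
    # the 4-neighbourhood of any column containing obstacle voxels
    gencol = np.zeros((nx, ny), dtype=np.bool_)
    lo_x = npml if "x-" in config.pml_faces else 1
    hi_x = npml if "x+" in config.pml_faces else 1
    lo_y = npml if "y-" in config.pml_faces else 1
    hi_y = npml if "y+" in config.pml_faces else 1
    gencol[:lo_x, :] = True
    gencol[nx - hi_x :, :] = True
    gencol[:, :lo_y] = True
    gencol[:, ny - hi_y :] = True
    floor_cells = int(round(config.floor_thickness / config.dx))
    obst = (mask[:, :, floor_cells:] != AIR).any(axis=2)
    if obst.any():
        grown = obst.copy()
        grown[1:, :] |= obst[:-1, :]
        grown[:-1, :] |= obst[1:, :]
        grown[:, 1:] |= obst[:, :-1]
        grown[:, :-1] |= obst[:, 1:]
        gencol |= grown
    k_lo = max(floor_cells + 1, npml if "z-" in config.pml_faces else 1)
    k_hi = nz - (npml if "z+" in config.pml_faces else 1)
    for n in range(n_steps):
        _update_psi(
            p1, psix, psiy, psiz, bx, ax, by, ay, bz, az, mask,
            0, npml, 0, npml, 0, npml,
        )
        _update_p(
            p0, p1, p2, psix, psiy, psiz, xix, xiy, xiz,
            bx, ax, by, ay, bz, az, mask, gencol, k_lo, k_hi, chi2, fcoef,
        )
        if n < len(waveform):
            p2[src] += waveform[n]
        trace[n + 1] = p2[rcv]
        if energies is not None and (n + 1) % energy_interval == 0:
            energies.append(_discrete_energy(p1, p2, mask, config.c, dt, config.dx * 1e-3))
        p0, p1, p2 = p1, p2, p0
        if (n + 1) % 100 == 0 or n == n_steps - 1:
            peak = float(np.abs(p1).max())
            if not np.isfinite(peak) or (amp > 0 and peak > 1e6 * amp):
                raise DivergenceError(f"field diverged at step {n + 1}: max |p| = {peak:.3e}")
    return ReceiverTrace(
        samples=np.asarray(trace),
        dt=dt,
        config_digest=config.digest(),
        source_position=tuple(config.source_position),
        receiver_position=tuple(config.receiver_position),
        energies=np.asarray(energies) if energies is not None else None,
    )
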