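"""Virtual-cell obstacle geometry: generation, indexing, Monte-Carlo sampling.

The model cell is a sphere of radius ``cell_radius`` whose interior is
crowded by two obstacle families: cylinders (a surrogate cytoskeleton,
treated as capsules around finite axis segments) and immobile spheres
(ribosome-scale crowders).  Obstacle centres are drawn uniformly in the cell
ball and cylinder orientations uniformly on the unit sphere; obstacles may
overlap each other and may protrude through the membrane, but only in-cell
volume counts toward occupancy statistics.

All lengths are micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels

#: Default reach margin of the spatial index: the largest probe radius for
#: which single-cell queries are guaranteed to see every relevant obstacle.
DEFAULT_REACH = 0.010

# The crowded model cell studied throughout: 7 um diameter, 25,000 cylinders
# of 2.5 um x 35 nm and 100,000 spheres of 60 nm diameter.
DEFAULT_CELL_RADIUS = 3.5
DEFAULT_N_CYLINDERS = 25_000
DEFAULT_CYL_LENGTH = 2.5
DEFAULT_CYL_RADIUS = 0.0175
DEFAULT_N_SPHERES = 100_000
DEFAULT_SPH_RADIUS = 0.030

#: Obstacle-count multiplier at which the Monte-Carlo excluded-volume
#: fraction for a 2.5 nm probe equals the 30.5 % operating point of the
#: default cell (measured once with ``calibrate_density``; see docs).
DEFAULT_DENSITY_MULTIPLIER = 0.790

#: Excluded-volume operating point for 2.5 nm tracers in the default cell.
TARGET_TRACER_EXCLUDED = 0.305
TRACER_RADIUS = 0.0025


@dataclass(frozen=True)
class Cylinder:
    """A capsule obstacle: finite axis segment of given length and radius."""

    center: tuple[float, float, float]
    axis: tuple[float, float, float]
    length: float
    radius: float

    def __post_init__(self):
        if self.length <= 0 or self.radius <= 0:
            raise ValueError("cylinder length and radius must be positive")
        n = math.sqrt(sum(a * a for a in self.axis))
        if abs(n - 1.0) > 1e-9:
            raise ValueError("cylinder axis must be a unit vector")


@dataclass(frozen=True)
class SphereObstacle:
    """An immobile spherical crowder."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")


@dataclass(frozen=True)
class VolumeSample:
    """A Monte-Carlo volume-fraction estimate with its binomial/sample SE."""

    fraction: float
    standard_error: float
    n_samples: int
    seed: int

    def __post_init__(self):
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must lie in [0, 1]")
        if self.standard_error < 0:
            raise ValueError("standard error must be non-negative")


class GridIndex:
    """Uniform-grid cell lists over the obstacle set (CSR layout)."""

    def __init__(self, geometry: "CellGeometry", cell_size: float,
                 reach: float):
        R = geometry.cell_radius
        self.cell_size = float(cell_size)
        self.reach = float(reach)
        pad = self.cell_size
        self.gmin = np.full(3, -(R + pad))
        extent = 2.0 * (R + pad)
        n = max(1, int(math.ceil(extent / self.cell_size)))
        self.n = (n, n, n)
        self.starts, self.entries = _kernels.build_grid(
            geometry.cyl_c, geometry.cyl_a, geometry.cyl_h, geometry.cyl_r,
            geometry.sph_c, geometry.sph_r,
            self.gmin, self.cell_size, n, n, n, self.reach)

    def query(self, point) -> np.ndarray:
        """Obstacle ids registered at the grid cell containing ``point``.

        Ids < n_cylinders are cylinders; the rest are sphere index + n_cyl.
        Points outside the grid return an empty set.
        """
        ijk = np.floor((np.asarray(point, float) - self.gmin)
                       / self.cell_size).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= self.n[0]):
            return np.empty(0, np.int32)
        cell = (ijk[0] * self.n[1] + ijk[1]) * self.n[2] + ijk[2]
        return self.entries[self.starts[cell]:self.starts[cell + 1]]


class CellGeometry:
    """The obstacle world: cell sphere, cylinder set, sphere set, index.

    Internally the obstacles are stored as flat float arrays (centres, axes,
    half-lengths, radii) so the numba kernels can consume them directly.
    """

    def __init__(self, cell_radius: float,
                 cyl_c=None, cyl_a=None, cyl_len=None, cyl_r=None,
                 sph_c=None, sph_r=None, grid_cell_size: float | None = None,
                 reach: float = DEFAULT_REACH):
        if cell_radius <= 0:
            raise ValueError("cell_radius must be positive")
        self.cell_radius = float(cell_radius)
        self.cyl_c = np.zeros((0, 3)) if cyl_c is None else np.atleast_2d(
            np.asarray(cyl_c, float))
        self.cyl_a = np.zeros((0, 3)) if cyl_a is None else np.atleast_2d(
            np.asarray(cyl_a, float))
        cyl_len = np.zeros(0) if cyl_len is None else np.atleast_1d(
            np.asarray(cyl_len, float))
        self.cyl_h = cyl_len / 2.0
        self.cyl_r = np.zeros(0) if cyl_r is None else np.atleast_1d(
            np.asarray(cyl_r, float))
        self.sph_c = np.zeros((0, 3)) if sph_c is None else np.atleast_2d(
            np.asarray(sph_c, float))
        self.sph_r = np.zeros(0) if sph_r is None else np.atleast_1d(
            np.asarray(sph_r, float))
        if np.any(self.cyl_h <= 0) and self.cyl_h.size:
            raise ValueError("cylinder lengths must be positive")
        if np.any(self.cyl_r <= 0) and self.cyl_r.size:
            raise ValueError("cylinder radii must be positive")
        if np.any(self.sph_r <= 0) and self.sph_r.size:
            raise ValueError("sphere radii must be positive")
        if self.cyl_a.size:
            norms = np.linalg.norm(self.cyl_a, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-9):
                raise ValueError("cylinder axes must be unit vectors")
        self.reach = float(reach)
        if grid_cell_size is None:
            r_max = 0.0
            if self.cyl_r.size:
                r_max = max(r_max, float(self.cyl_r.max()))
            if self.sph_r.size:
                r_max = max(r_max, float(self.sph_r.max()))
            grid_cell_size = max(r_max + self.reach,
                                 2.0 * self.cell_radius / 140.0)
        if grid_cell_size <= 0:
            raise ValueError("grid_cell_size must be positive")
        self.grid_cell_size = float(grid_cell_size)
        self._index: GridIndex | None = None

    # -- convenience views -------------------------------------------------
    @property
    def n_cylinders(self) -> int:
        return self.cyl_r.shape[0]

    @property
    def n_spheres(self) -> int:
        return self.sph_r.shape[0]

    @property
    def cylinders(self) -> list[Cylinder]:
        return [Cylinder(tuple(self.cyl_c[i]), tuple(self.cyl_a[i]),
                         2.0 * self.cyl_h[i], self.cyl_r[i])
                for i in range(self.n_cylinders)]

    @property
    def spheres(self) -> list[SphereObstacle]:
        return [SphereObstacle(tuple(self.sph_c[i]), self.sph_r[i])
                for i in range(self.n_spheres)]

    @property
    def cell_volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.cell_radius ** 3

    # -- spatial index -----------------------------------------------------
    @property
    def index(self) -> GridIndex:
        if self._index is None:
            self._index = GridIndex(self, self.grid_cell_size, self.reach)
        return self._index

    def kernel_args(self):
        """The flat tuple every numba kernel takes to describe this world."""
        idx = self.index
        return (self.cell_radius, self.cyl_c, self.cyl_a, self.cyl_h,
                self.cyl_r, self.sph_c, self.sph_r, idx.gmin, idx.cell_size,
                idx.n[0], idx.n[1], idx.n[2], idx.starts, idx.entries)

    # -- queries -----------------------------------------------------------
    def is_accessible(self, point, probe_radius: float) -> bool:
        """True iff a probe sphere at ``point`` is inside the cell and does
        not overlap any obstacle (grid-accelerated)."""
        if probe_radius < 0:
            raise ValueError("probe_radius must be non-negative")
        if probe_radius > self.reach:
            return self.is_accessible_bruteforce(point, probe_radius)
        p = np.asarray(point, float)
        return bool(_kernels._point_free(p[0], p[1], p[2], probe_radius,
                                         *self.kernel_args()))

    def is_accessible_bruteforce(self, point, probe_radius: float) -> bool:
        """Reference implementation scanning every obstacle (no index)."""
        p = np.asarray(point, float)
        if np.linalg.norm(p) + probe_radius > self.cell_radius:
            return False
        if self.n_cylinders:
            v = p - self.cyl_c
            t = np.einsum("ij,ij->i", v, self.cyl_a)
            t = np.clip(t, -self.cyl_h, self.cyl_h)
            d2 = np.sum((v - t[:, None] * self.cyl_a) ** 2, axis=1)
            if np.any(d2 < (self.cyl_r + probe_radius) ** 2):
                return False
        if self.n_spheres:
            d2 = np.sum((p - self.sph_c) ** 2, axis=1)
            if np.any(d2 < (self.sph_r + probe_radius) ** 2):
                return False
        return True

    # -- Monte-Carlo samplers ----------------------------------------------
    def sample_excluded_fraction(self, probe_radius: float, n_samples: int,
                                 seed: int) -> VolumeSample:
        """Fraction of the cell ball blocked for a probe of given radius."""
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        blocked = _kernels._sample_excluded(n_samples, probe_radius,
                                            seed, *self.kernel_args())
        f = blocked / n_samples
        se = math.sqrt(max(f * (1.0 - f), 1.0 / n_samples) / n_samples)
        return VolumeSample(f, se, n_samples, seed)

    def sample_access_factor(self, r_i: float, r_j: float, n_centers: int,
                             n_shell: int, seed: int,
                             max_tries: int = 100_000) -> VolumeSample:
        """Mean accessible fraction of the pairwise interaction volume.

        Draws ``n_centers`` positions accessible to a probe of radius
        ``r_i``; around each, scores ``n_shell`` uniform points of the ball
        of radius ``r_i + r_j`` for accessibility to a probe of radius
        ``r_j``.  This is the geometric accessibility correction f_access.
        """
        if r_i <= 0 or r_j <= 0:
            raise ValueError("probe radii must be positive")
        if n_centers < 1 or n_shell < 1:
            raise ValueError("sample counts must be >= 1")
        mean, m2, n_done = _kernels._sample_access(
            n_centers, n_shell, r_i, r_j, seed, max_tries,
            *self.kernel_args())
        if n_done < n_centers:
            raise RuntimeError(
                "accessible-centre sampling saturated: geometry too dense "
                f"(placed {n_done}/{n_centers} centres)")
        se = math.sqrt(m2 / n_done / max(n_done - 1, 1)) if n_done > 1 else 0.0
        return VolumeSample(mean, se, n_centers * n_shell, seed)

    def effective_surface_area(self, probe_radius: float, n_samples: int,
                               seed: int) -> float:
        """Obstacle surface area (um^2) reachable by a probe, Monte-Carlo.

        Samples surface points proportional to nominal area (cylinder
        lateral surfaces and sphere surfaces) and keeps the fraction whose
        probe-contact position is accessible; buried or out-of-cell surface
        is thereby discounted.  Used to convert a bulk binding rate into an
        intrinsic surface velocity.
        """
        areas = np.concatenate([
            2.0 * math.pi * self.cyl_r * (2.0 * self.cyl_h),
            4.0 * math.pi * self.sph_r ** 2])
        if areas.size == 0 or areas.sum() == 0.0:
            return 0.0
        cum = np.cumsum(areas)
        hits = _kernels._sample_surface_accessible(
            n_samples, probe_radius, seed, cum, *self.kernel_args())
        return float(cum[-1] * hits / n_samples)

    # -- serialization -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_cylinders):
            rows.append(("cylinder", *self.cyl_c[i], *self.cyl_a[i],
                         2.0 * self.cyl_h[i], self.cyl_r[i]))
        for i in range(self.n_spheres):
            rows.append(("sphere", *self.sph_c[i], 0.0, 0.0, 0.0,
                         0.0, self.sph_r[i]))
        return pd.DataFrame(rows, columns=["type", "cx", "cy", "cz",
                                           "ax", "ay", "az",
                                           "length", "radius"])

    def save_csv(self, path) -> None:
        frame = self.to_frame()
        for col in frame.columns[1:]:
            frame[col] = frame[col].map(repr)  # bit-exact float round-trip
        with open(path, "w") as fh:
            fh.write(f"# cell_radius={self.cell_radius!r} "
                     f"grid_cell_size={self.grid_cell_size!r}\n")
            frame.to_csv(fh, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, cell_radius: float,
                   grid_cell_size: float | None = None) -> "CellGeometry":
        cyl = frame[frame["type"] == "cylinder"]
        sph = frame[frame["type"] == "sphere"]
        return cls(cell_radius,
                   cyl_c=cyl[["cx", "cy", "cz"]].to_numpy(float),
                   cyl_a=cyl[["ax", "ay", "az"]].to_numpy(float),
                   cyl_len=cyl["length"].to_numpy(float),
                   cyl_r=cyl["radius"].to_numpy(float),
                   sph_c=sph[["cx", "cy", "cz"]].to_numpy(float),
                   sph_r=sph["radius"].to_numpy(float),
                   grid_cell_size=grid_cell_size)

    @classmethod
    def load_csv(cls, path) -> "CellGeometry":
        with open(path) as fh:
            header = fh.readline().strip()
            meta = dict(kv.split("=") for kv in
                        header.lstrip("# ").split())
            frame = pd.read_csv(fh, float_precision="round_trip")
        return cls.from_frame(frame, float(meta["cell_radius"]),
                              float(meta["grid_cell_size"]))


def generate_geometry(cell_radius: float, n_cylinders: int, cyl_length: float,
                      cyl_radius: float, n_spheres: int, sph_radius: float,
                      seed: int, density_multiplier: float = 1.0,
                      grid_cell_size: float | None = None) -> CellGeometry:
    """Draw a random obstacle world.

    Cylinder centres and sphere centres are uniform in the cell ball and
    cylinder orientations uniform on the unit sphere; obstacles may overlap
    each other and stick out through the membrane.  ``density_multiplier``
    scales both obstacle counts (the calibration knob for the excluded
    volume fraction).  Deterministic for a fixed seed.
    """
    if cell_radius <= 0:
        raise ValueError("cell_radius must be positive")
    if n_cylinders < 0 or n_spheres < 0:
        raise ValueError("obstacle counts must be non-negative")
    if n_cylinders and (cyl_length <= 0 or cyl_radius <= 0):
        raise ValueError("cylinder dimensions must be positive")
    if n_spheres and sph_radius <= 0:
        raise ValueError("sphere dimensions must be positive")
    if density_multiplier < 0:
        raise ValueError("density_multiplier must be non-negative")
    rng = np.random.default_rng(seed)
    ncyl = int(round(n_cylinders * density_multiplier))
    nsph = int(round(n_spheres * density_multiplier))

    def _uniform_ball(n):
        v = rng.standard_normal((n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = cell_radius * rng.random(n) ** (1.0 / 3.0)
        return v * r[:, None]

    cyl_c = _uniform_ball(ncyl)
    axes = rng.standard_normal((ncyl, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    sph_c = _uniform_ball(nsph)
    return CellGeometry(
        cell_radius,
        cyl_c=cyl_c, cyl_a=axes,
        cyl_len=np.full(ncyl, cyl_length), cyl_r=np.full(ncyl, cyl_radius),
        sph_c=sph_c, sph_r=np.full(nsph, sph_radius),
        grid_cell_size=grid_cell_size)


def build_spatial_index(geometry: CellGeometry) -> CellGeometry:
    """Force construction of the uniform-grid index; returns the geometry."""
    geometry.index  # noqa: B018 - building is the side effect
    return geometry


def calibrate_density(target: float = TARGET_TRACER_EXCLUDED,
                      probe_radius: float = TRACER_RADIUS,
                      cell_radius: float = DEFAULT_CELL_RADIUS,
                      n_cylinders: int = DEFAULT_N_CYLINDERS,
                      cyl_length: float = DEFAULT_CYL_LENGTH,
                      cyl_radius: float = DEFAULT_CYL_RADIUS,
                      n_spheres: int = DEFAULT_N_SPHERES,
                      sph_radius: float = DEFAULT_SPH_RADIUS,
                      seed: int = 2011, n_samples: int = 200_000,
                      tol: float = 0.002, max_iter: int = 12) -> float:
    """Find the obstacle-count multiplier whose Monte-Carlo probe-excluded
    fraction matches ``target`` (secant iteration on the multiplier)."""
    def measure(mult):
        g = generate_geometry(cell_radius, n_cylinders, cyl_length,
                              cyl_radius, n_spheres, sph_radius, seed,
                              density_multiplier=mult)
        return g.sample_excluded_fraction(probe_radius, n_samples,
                                          seed + 1).fraction

    m0, m1 = 0.7, 1.0
    f0, f1 = measure(m0), measure(m1)
    for _ in range(max_iter):
        if abs(f1 - target) <= tol:
            return m1
        slope = (f1 - f0) / (m1 - m0)
        m0, f0 = m1, f1
        m1 = m1 + (target - f1) / slope
        m1 = max(0.05, m1)
        f1 = measure(m1)
    return m1


def default_cell_geometry(seed: int = 2011,
                   density_multiplier: float | None = None) -> CellGeometry:
    """The default crowded model cell at its calibrated operating point."""
    mult = (DEFAULT_DENSITY_MULTIPLIER if density_multiplier is None
            else density_multiplier)
    return generate_geometry(DEFAULT_CELL_RADIUS, DEFAULT_N_CYLINDERS,
                             DEFAULT_CYL_LENGTH, DEFAULT_CYL_RADIUS,
                             DEFAULT_N_SPHERES, DEFAULT_SPH_RADIUS,
                             seed, density_multiplier=mult)
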