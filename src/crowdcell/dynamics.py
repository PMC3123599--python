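"""Mobile agents: species parameters, particle state, the rejection walk.

Each unbound mobile particle makes an independent Gaussian step with
per-axis variance ``2*D0*dt``; a step whose endpoint would overlap an
obstacle or leave the cell is rejected wholesale and the particle waits for
the next timestep.  Bound particles (adsorbed to a structure) and immobile
species (D0 = 0) never move.  Mobile particles are allowed to overlap one
another; excluded volume acts only between particles and structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .geometry import CellGeometry

INIT_DISTRIBUTIONS = ("uniform_accessible", "membrane_layer",
                      "channel_segment", "fixed_positions")


@dataclass(frozen=True)
class SpeciesSpec:
    """Physical parameters and initial population of one molecular species."""

    name: str
    radius: float
    D0: float
    init_count: int = 0
    init_distribution: str = "uniform_accessible"
    #: shell thickness for membrane_layer placement (um)
    shell_thickness: float = 0.05
    #: polar-angle band (cos_theta_hi, cos_theta_lo) for channel_segment
    segment: tuple | None = None
    positions: tuple | None = None

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("species radius must be positive")
        if self.D0 < 0:
            raise ValueError("D0 must be non-negative")
        if self.init_count < 0:
            raise ValueError("init_count must be non-negative")
        if self.init_distribution not in INIT_DISTRIBUTIONS:
            raise ValueError(
                f"unknown init_distribution {self.init_distribution!r}")

    @property
    def mobile(self) -> bool:
        return self.D0 > 0


class ParticleSystem:
    """Struct-of-arrays particle state over a fixed species table."""

    def __init__(self, species: list[SpeciesSpec], capacity: int = 0):
        self.species = {s.name: s for s in species}
        self.species_index = {s.name: k for k, s in enumerate(species)}
        self.species_list = list(species)
        n = max(capacity, 1)
        self.positions = np.zeros((n, 3))
        self.species_id = np.zeros(n, np.int32)
        self.bound = np.zeros(n, bool)
        self.alive = np.zeros(n, bool)
        self.n_used = 0

    # -- views -------------------------------------------------------------
    @property
    def species_name(self) -> np.ndarray:
        names = np.array([s.name for s in self.species_list])
        return names[self.species_id]

    @property
    def radius(self) -> np.ndarray:
        r = np.array([s.radius for s in self.species_list])
        return r[self.species_id]

    def count(self, name: str) -> int:
        return int(np.sum(self.alive
                          & (self.species_id == self.species_index[name])))

    # -- mutation ----------------------------------------------------------
    def _grow(self, need: int):
        cap = self.positions.shape[0]
        if need <= cap:
            return
        new = max(need, 2 * cap)
        self.positions = np.resize(self.positions, (new, 3))
        self.species_id = np.resize(self.species_id, new)
        self.bound = np.resize(self.bound, new)
        self.alive = np.resize(self.alive, new)

    def spawn(self, name: str, position, bound: bool = False) -> int:
        self._grow(self.n_used + 1)
        i = self.n_used
        self.positions[i] = position
        self.species_id[i] = self.species_index[name]
        self.bound[i] = bound
        self.alive[i] = True
        self.n_used += 1
        return i

    def set_species(self, idx: int, name: str):
        self.species_id[idx] = self.species_index[name]

    def place_initial(self, geometry: CellGeometry,
                      rng: np.random.Generator):
        """Draw the initial positions of every species' population."""
        for s in self.species_list:
            if s.init_count == 0:
                continue
            if s.init_distribution == "fixed_positions":
                pts = np.asarray(s.positions, float)
                if pts.shape != (s.init_count, 3):
                    raise ValueError("fixed_positions shape mismatch")
                for p in pts:
                    self.spawn(s.name, p)
                continue
            for p in sample_positions(geometry, s, s.init_count, rng):
                self.spawn(s.name, p)


def sample_positions(geometry: CellGeometry, spec: SpeciesSpec, n: int,
                     rng: np.random.Generator,
                     max_tries: int = 200_000) -> np.ndarray:
    """Rejection-sample ``n`` accessible positions for a species.

    uniform_accessible draws uniformly over the whole accessible volume;
    membrane_layer restricts to a shell of given thickness under the
    membrane; channel_segment further restricts to a polar-angle band
    (``segment`` = interval of cos(theta), used for ordered enzyme
    channels).
    """
    R = geometry.cell_radius - spec.radius
    a = R
    if spec.init_distribution in ("membrane_layer", "channel_segment"):
        a = max(R - spec.shell_thickness, 0.0)
    else:
        a = 0.0
    out = np.empty((n, 3))
    have = 0
    for _ in range(max_tries):
        if have >= n:
            break
        rr = (a ** 3 + rng.random() * (R ** 3 - a ** 3)) ** (1.0 / 3.0)
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        if spec.init_distribution == "channel_segment" and spec.segment:
            hi, lo = max(spec.segment), min(spec.segment)
            cos_t = v[2]
            if not (lo <= cos_t <= hi):
                continue
        p = v * rr
        if geometry.is_accessible(p, spec.radius):
            out[have] = p
            have += 1
    if have < n:
        raise RuntimeError(f"could only place {have}/{n} particles; "
                           "geometry too dense or segment too narrow")
    return out


def diffusion_step(system: ParticleSystem, geometry: CellGeometry,
                   dt: float, rng: np.random.Generator) -> int:
    """One rejection-sampled Gaussian step for every unbound mobile particle.

    Returns the number of accepted moves.  numpy reference implementation;
    the engine uses the fused numba kernel for long runs.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    accepted = 0
    D = np.array([s.D0 for s in system.species_list])
    for i in range(system.n_used):
        if not system.alive[i] or system.bound[i]:
            continue
        D0 = D[system.species_id[i]]
        if D0 == 0.0:
            continue
        step = rng.standard_normal(3) * np.sqrt(2.0 * D0 * dt)
        trial = system.positions[i] + step
        if geometry.is_accessible(trial, system.radius[i]):
            system.positions[i] = trial
            accepted += 1
    return accepted


@dataclass
class Trajectories:
    """Recorded tracer trajectories on a uniform schedule."""

    times: np.ndarray          # (T,)
    positions: np.ndarray      # (T, N, 3)
    bound: np.ndarray          # (T, N)
    species: str = "tracer"

    def to_frame(self) -> pd.DataFrame:
        T, N, _ = self.positions.shape
        return pd.DataFrame({
            "time": np.repeat(self.times, N),
            "particle": np.tile(np.arange(N), T),
            "species": self.species,
            "x": self.positions[:, :, 0].ravel(),
            "y": self.positions[:, :, 1].ravel(),
            "z": self.positions[:, :, 2].ravel(),
            "bound": self.bound.ravel(),
        })

    def unbound_fraction(self) -> np.ndarray:
        return 1.0 - self.bound.mean(axis=1)


def run_tracers(geometry: CellGeometry, spec: SpeciesSpec, n: int,
                t_end: float, dt: float, record_every: int, seed: int,
                kappa_ads: float = 0.0, k_diss: float = 0.0,
                bind_membrane: bool = False, bind_structures: bool = True,
                start_bound: bool = False) -> Trajectories:
    """Propagate ``n`` inert tracers and record their trajectories.

    Optional transient binding: an unbound tracer whose surface gap to a
    structure is below ``kappa_ads*dt`` is immobilized; bound tracers are
    released with probability ``k_diss*dt`` per step.  Deterministic for a
    fixed seed.
    """
    if t_end < dt:
        raise ValueError("t_end must be at least dt")
    rng = np.random.default_rng(seed)
    pos = sample_positions(geometry, spec, n, rng)
    bound = np.full(n, start_bound)
    n_steps = int(round(t_end / dt))
    n_rec = n_steps // record_every + 1
    out_pos = np.empty((n_rec, n, 3))
    out_bound = np.zeros((n_rec, n), bool)
    kernel_seed = int(rng.integers(1, 2**31 - 1))
    _kernels._tracer_run(pos, bound, spec.radius, spec.D0, dt, n_steps,
                         record_every, kappa_ads, k_diss, bind_membrane,
                         bind_structures, kernel_seed,
                         *geometry.kernel_args(), out_pos, out_bound)
    times = np.arange(n_rec) * record_every * dt
    return Trajectories(times, out_pos, out_bound, spec.name)
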