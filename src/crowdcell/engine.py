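"""The time loop: diffusion, binding, reactions, observation — reproducibly.

Per timestep the engine applies, in fixed order: the rejection random walk,
adsorption/dissociation, bimolecular sweeps (candidate pairs visited in
uniformly random order, each particle in at most one reaction per step),
unimolecular conversions, zero-order creation, membrane export, and then
records observations.  Runs are bit-reproducible for a fixed seed, and the
observation schedule never consumes random numbers, so changing it does not
change the dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .dynamics import ParticleSystem, SpeciesSpec
from .geometry import CellGeometry
from .reactions import (CONC_FACTOR, BimolecularKernel, ReactionSpec,
                        collision_rate_kD)


@dataclass
class SimulationConfig:
    """Everything a run needs: world, populations, channels, schedule."""

    geometry: CellGeometry
    species: list
    reactions: list = field(default_factory=list)
    dt: float = 1.0e-5
    t_end: float = 1.0
    seed: int = 0
    observation_interval: float | None = None
    steady_state_window: tuple | None = None
    capacity: int | None = None

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_end < self.dt:
            raise ValueError("t_end must be at least dt")
        if self.observation_interval is None:
            self.observation_interval = max(self.t_end / 200.0, self.dt)
        if self.observation_interval < self.dt:
            raise ValueError("observation_interval must be >= dt")
        if self.steady_state_window is not None:
            lo, hi = self.steady_state_window
            if not (0 <= lo < hi <= self.t_end):
                raise ValueError("steady_state_window outside [0, t_end]")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")

    def bimolecular_kernels(self) -> dict:
        """Derived (k_D, k_micro, R_crit, P_react) per bimolecular channel.

        Raises before any stepping if a probability would exceed 1.
        """
        spmap = {s.name: s for s in self.species}
        out = {}
        for r in self.reactions:
            if r.kind != "bimolecular":
                continue
            a, b = (spmap[r.educts[0]], spmap[r.educts[1]])
            out[r.name] = BimolecularKernel.from_rates(
                r.k_macro, a.radius, b.radius, a.D0, b.D0, self.dt,
                kD_reference=r.kD_reference)
        return out


@dataclass
class ObservableSeries:
    """Time-stamped species counts, bound counts and cumulative events."""

    times: np.ndarray
    species_names: list
    counts: np.ndarray        # (T, S)
    bound_counts: np.ndarray  # (T, S)
    channel_names: list
    events: np.ndarray        # (T, C) cumulative
    config: SimulationConfig | None = None

    def count(self, name: str) -> np.ndarray:
        return self.counts[:, self.species_names.index(name)]

    def bound_count(self, name: str) -> np.ndarray:
        return self.bound_counts[:, self.species_names.index(name)]

    def event_count(self, channel: str) -> np.ndarray:
        return self.events[:, self.channel_names.index(channel)]

    def unbound_fraction(self, name: str) -> np.ndarray:
        tot = self.count(name)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, 1.0 - self.bound_count(name) / tot,
                            np.nan)

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.times,
                                                        name="time"),
                            columns=self.species_names)

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, index=pd.Index(self.times,
                                                        name="time"),
                            columns=self.channel_names)


def _compile_channels(config: SimulationConfig):
    """Translate ReactionSpecs into the flat arrays the kernel consumes."""
    sp_index = {s.name: k for k, s in enumerate(config.species)}
    S = len(config.species)
    geom = config.geometry
    dt = config.dt

    sp_radius = np.array([s.radius for s in config.species])
    sp_D = np.array([s.D0 for s in config.species])
    sp_kads = np.zeros(S)
    sp_kdiss = np.zeros(S)
    sp_bind_mem = np.zeros(S, bool)
    sp_bind_str = np.zeros(S, bool)

    bi, un, ze, ex = [], [], [], []
    # event columns follow the kernel layout: bimolecular, unimolecular,
    # zero-order, export — regardless of the order in config.reactions
    names_bi, names_un, names_ze, names_ex = [], [], [], []
    kernels = config.bimolecular_kernels()
    for r in config.reactions:
        if r.kind == "bimolecular":
            from .reactions import _bimolecular_product_slots
            p1, p2 = _bimolecular_product_slots(r)
            k = kernels[r.name]
            bi.append((sp_index[r.educts[0]], sp_index[r.educts[1]],
                       k.R_crit ** 2, k.P_react,
                       -1 if p1 is None else sp_index[p1],
                       -1 if p2 is None else sp_index[p2]))
            names_bi.append(r.name)
        elif r.kind in ("unimolecular",):
            prods = list(r.products)
            p1 = sp_index[prods[0]] if prods else -1
            p2 = sp_index[prods[1]] if len(prods) > 1 else -1
            un.append((sp_index[r.educts[0]], r.k_macro * dt, p1, p2))
            names_un.append(r.name)
        elif r.kind in ("zero_order", "membrane_influx"):
            if r.molecules_per_s is not None:
                lam = r.molecules_per_s * dt
            else:
                lam = r.k_macro * CONC_FACTOR * geom.cell_volume * dt
            region = 1 if (r.kind == "membrane_influx"
                           or r.region == "membrane_shell") else 0
            ze.append((sp_index[r.products[0]], lam, region,
                       r.shell_thickness))
            names_ze.append(r.name)
        elif r.kind == "membrane_export":
            layer = (r.capture_layer if r.capture_layer is not None
                     else r.k_macro * dt)
            ex.append((sp_index[r.educts[0]], layer))
            names_ex.append(r.name)
        elif r.kind == "adsorption":
            s = sp_index[r.educts[0]]
            sp_kads[s] = r.k_macro
            sp_bind_str[s] = r.bind_structures
            sp_bind_mem[s] = r.bind_membrane
            obstacle_radii = np.concatenate([geom.cyl_r, geom.sph_r])
            if (r.bind_structures and obstacle_radii.size
                    and r.k_macro * dt >= obstacle_radii.min()):
                raise ValueError("adsorption layer kappa*dt must stay far "
                                 "below the smallest obstacle radius")
        elif r.kind == "dissociation":
            s = sp_index[r.educts[0]]
            if r.k_macro * dt > 1.0:
                raise ValueError("k_diss*dt must not exceed 1")
            sp_kdiss[s] = r.k_macro
        else:  # pragma: no cover - guarded by ReactionSpec
            raise ValueError(r.kind)

    channel_names = names_bi + names_un + names_ze + names_ex

    # species that provably never move, appear, or change (immobile and only
    # ever catalytic) can live in a pair grid built once per run
    sp_static = np.array([s.D0 == 0.0 for s in config.species]) \
        & (sp_kads == 0.0)
    for r in config.reactions:
        for k, s in enumerate(config.species):
            if not sp_static[k]:
                continue
            if r.kind == "bimolecular":
                catalytic = s.name in r.educts and s.name in r.products
                if (s.name in r.educts or s.name in r.products) \
                        and not catalytic:
                    sp_static[k] = False
            elif s.name in r.educts or s.name in r.products:
                sp_static[k] = False
    # scan bimolecular channels from the mobile educt's side; a channel
    # between two immobile educts falls back to the dynamic path
    for row_idx in range(len(bi)):
        e1, e2, r2, p, p1, p2 = bi[row_idx]
        if sp_static[e1] and sp_static[e2]:
            sp_static[e1] = False
            sp_static[e2] = False
        elif sp_static[e1]:
            bi[row_idx] = (e2, e1, r2, p, p2, p1)

    def pack(rows, dtypes):
        if not rows:
            return tuple(np.zeros(0, d) for d in dtypes)
        cols = list(zip(*rows))
        return tuple(np.asarray(c, d) for c, d in zip(cols, dtypes))

    bi_arr = pack(bi, (np.int32, np.int32, float, float, np.int32, np.int32))
    un_arr = pack(un, (np.int32, float, np.int32, np.int32))
    ze_arr = pack(ze, (np.int32, float, np.int32, float))
    ex_arr = pack(ex, (np.int32, float))
    species_arrays = (sp_radius, sp_D, sp_kads, sp_kdiss, sp_bind_mem,
                      sp_bind_str, sp_static)
    return species_arrays, bi_arr, un_arr, ze_arr, ex_arr, channel_names


def run(config: SimulationConfig) -> ObservableSeries:
    """Execute a configured simulation; deterministic for a fixed seed."""
    geom = config.geometry
    dt = config.dt
    n_steps = int(round(config.t_end / dt))
    obs_every = max(1, int(round(config.observation_interval / dt)))
    n_obs = n_steps // obs_every + 1

    (species_arrays, bi_arr, un_arr, ze_arr, ex_arr,
     channel_names) = _compile_channels(config)

    rng = np.random.default_rng(config.seed)
    n_init = sum(s.init_count for s in config.species)
    expected_new = float(np.sum(ze_arr[1]) * n_steps) if ze_arr[1].size \
        else 0.0
    # unimolecular channels with two products can also grow the population
    if un_arr[0].size and np.any(un_arr[3] >= 0):
        expected_new += n_init  # generous headroom for splitting channels
    capacity = config.capacity or int(n_init + 2.0 * expected_new + 256)

    system = ParticleSystem(config.species, capacity)
    system.place_initial(geom, rng)
    system._grow(capacity)

    rcrit_max = math.sqrt(float(bi_arr[2].max())) if bi_arr[2].size else 0.0
    R = geom.cell_radius
    sp_static = species_arrays[-1]
    n_static = sum(s.init_count for k, s in enumerate(config.species)
                   if sp_static[k])
    n_mobile_cap = capacity - n_static

    def grid_side(n_particles):
        if rcrit_max <= 0:
            return 1
        return max(1, min(int(2 * R / rcrit_max),
                          max(4, int(math.ceil((4.0 * max(n_particles, 1))
                                               ** (1 / 3))))))

    n_side = grid_side(n_mobile_cap)
    pg_h = 2.0 * R / n_side
    pg_n = n_side + 2
    st_side = grid_side(n_static)
    st_h = 2.0 * R / st_side
    st_n = st_side + 2

    S = len(config.species)
    n_ch = len(channel_names)
    out_counts = np.zeros((n_obs, S), np.int64)
    out_bound = np.zeros((n_obs, S), np.int64)
    out_events = np.zeros((n_obs, max(n_ch, 1)), np.int64)

    kernel_seed = int(rng.integers(1, 2 ** 31 - 1))
    n_used, overflow, placement_fail = _kernels._advance(
        system.positions, system.species_id, system.bound, system.alive,
        system.n_used, *species_arrays, dt, n_steps, obs_every, kernel_seed,
        *geom.kernel_args(), *bi_arr, *un_arr, *ze_arr, *ex_arr,
        pg_n, pg_h, st_n, st_h, out_counts, out_bound, out_events)
    system.n_used = int(n_used)
    if overflow:
        raise RuntimeError("particle capacity or pair buffer exceeded; "
                           "increase config.capacity")
    if placement_fail:
        raise RuntimeError("zero-order placement saturated (geometry too "
                           "dense for rejection sampling)")

    times = np.arange(n_obs) * obs_every * dt
    return ObservableSeries(times, [s.name for s in config.species],
                            out_counts, out_bound, channel_names,
                            out_events[:, :n_ch], config)


def steady_state_average(series: ObservableSeries, species: str,
                         window: tuple | None = None):
    """Mean, SD and autocorrelation-robust SE of a count over a window.

    The SE uses block averaging (16 blocks) so that correlated samples do
    not understate the uncertainty.  ``window`` defaults to the config's
    ``steady_state_window``; it must exclude the relaxation transient.
    """
    if window is None and series.config is not None:
        window = series.config.steady_state_window
    if window is None:
        raise ValueError("no steady-state window given")
    lo, hi = window
    sel = (series.times >= lo) & (series.times <= hi)
    x = series.count(species)[sel].astype(float)
    if x.size == 0:
        raise ValueError("steady-state window contains no samples")
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    nb = max(min(16, x.size // 2), 1)
    if nb > 1:
        blocks = np.array_split(x, nb)
        bm = np.array([b.mean() for b in blocks])
        se = float(bm.std(ddof=1) / np.sqrt(nb))
    else:
        se = 0.0
    return mean, sd, se
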