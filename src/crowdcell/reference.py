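"""Well-mixed references and the crowding-correction calculus.

A bimolecular rate measured in a dilute assay shifts in the crowded cell by
three multiplicative factors:

    f_vol    = 1/(1-eps)                 excluded volume raises the
                                         effective concentration
    f_diff   = delta/(beta + delta*(1-beta))
                                         reduced mobility lowers the
                                         collision rate (beta = k/k_D,
                                         delta = D_eff/D0)
    f_access geometric accessibility of the pairwise interaction volume,
             sampled by Monte Carlo on the obstacle geometry
    f_eff    = f_vol * f_diff * f_access

For the enzymatic test model  0 -> S  (rate k1),  S + E -> P + E  (rate k2)
the well-mixed steady state is c_S = k1/(k2*c_E); in the crowded cell k2 is
replaced by f_eff*k2.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass

import numpy as np

from .engine import ObservableSeries, SimulationConfig
from .geometry import CellGeometry
from .reactions import CONC_FACTOR, ReactionSpec, collision_rate_kD


def f_vol(epsilon: float) -> float:
    """Concentration factor from the excluded volume fraction."""
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must lie in [0, 1)")
    return 1.0 / (1.0 - epsilon)


def f_diff(beta: float, delta: float) -> float:
    """Rate reduction from slowed diffusion.

    ``beta = k_macro/k_D`` is the degree of diffusion limitation and
    ``delta = D_eff/D0`` the mobility reduction; holding k_micro fixed while
    k_D scales with delta gives ``f_diff = delta/(beta + delta*(1-beta))``.
    """
    if not 0.0 <= beta < 1.0:
        raise ValueError("beta must lie in [0, 1)")
    if not 0.0 < delta <= 1.0:
        raise ValueError("delta must lie in (0, 1]")
    return delta / (beta + delta * (1.0 - beta))


@dataclass(frozen=True)
class CrowdingFactors:
    """The (eps, beta, delta, f_vol, f_diff, f_access, f_eff) bundle."""

    epsilon: float
    beta: float
    delta: float
    f_access: float = 1.0

    @property
    def f_vol(self) -> float:
        return f_vol(self.epsilon)

    @property
    def f_diff(self) -> float:
        return f_diff(self.beta, self.delta)

    @property
    def f_eff(self) -> float:
        return self.f_vol * self.f_diff * self.f_access

    def as_dict(self) -> dict:
        return {"epsilon": self.epsilon, "beta": self.beta,
                "delta": self.delta, "f_vol": self.f_vol,
                "f_diff": self.f_diff, "f_access": self.f_access,
                "f_eff": self.f_eff}


def f_eff(factors: CrowdingFactors) -> float:
    """Combined effective-rate factor f_vol * f_diff * f_access."""
    return factors.f_eff


def ode_steady_state(k1: float, k2: float, cE: float,
                     n_enzymes: int | None = None,
                     f_eff: float = 1.0):
    """Steady state of the enzymatic test model, c_S = k1/(f_eff*k2*cE).

    Returns ``(c_S, count)``; the molecule count uses the enzyme
    bookkeeping convention ``count = (c_S/cE) * n_enzymes`` (the cell
    volume implied by holding n_enzymes at concentration cE).  With
    ``f_eff`` != 1 this is the crowded in-vivo prediction.
    """
    if k2 * cE <= 0 or f_eff <= 0:
        raise ValueError("k2*cE and f_eff must be positive")
    c_s = k1 / (f_eff * k2 * cE)
    count = None
    if n_enzymes is not None:
        count = c_s / cE * n_enzymes
    return c_s, count


@dataclass(frozen=True)
class MassActionReaction:
    """One well-mixed channel for the stochastic (Gillespie) reference.

    ``rate`` units: mol/(L s) for order 0, 1/s for order 1, L/(mol s) for
    order 2.  ``educts``/``products`` are species-name tuples.
    """

    educts: tuple
    products: tuple
    rate: float
    name: str = ""

    def __post_init__(self):
        if not self.name:
            lhs = "+".join(self.educts) or "0"
            rhs = "+".join(self.products) or "0"
            object.__setattr__(self, "name", f"{lhs}->{rhs}")

    @property
    def order(self) -> int:
        return len(self.educts)


def gillespie_run(reactions: list, initial_counts: dict, volume: float,
                  t_end: float, seed: int,
                  record_times=None) -> ObservableSeries:
    """Exact SSA (direct method) for a well-mixed mass-action network.

    ``volume`` in um^3 converts between counts and concentrations.  Counts
    are recorded on ``record_times`` (default: 200 uniform points).
    """
    names = sorted({s for r in reactions for s in (*r.educts, *r.products)}
                   | set(initial_counts))
    idx = {n: k for k, n in enumerate(names)}
    x = np.zeros(len(names), np.int64)
    for n, c in initial_counts.items():
        x[idx[n]] = c
    stoich = np.zeros((len(reactions), len(names)), np.int64)
    cprop = np.empty(len(reactions))
    for k, r in enumerate(reactions):
        for e in r.educts:
            stoich[k, idx[e]] -= 1
        for p in r.products:
            stoich[k, idx[p]] += 1
        if r.order == 0:
            cprop[k] = r.rate * CONC_FACTOR * volume
        elif r.order == 1:
            cprop[k] = r.rate
        elif r.order == 2:
            cprop[k] = r.rate / (CONC_FACTOR * volume)
        else:
            raise ValueError("mass action up to order 2 only")
    if record_times is None:
        record_times = np.linspace(0.0, t_end, 201)
    record_times = np.asarray(record_times, float)
    out = np.zeros((record_times.size, len(names)), np.int64)
    ev = np.zeros(len(reactions), np.int64)
    out_ev = np.zeros((record_times.size, len(reactions)), np.int64)
    rng = np.random.default_rng(seed)
    t = 0.0
    rec = 0
    while True:
        a = np.empty(len(reactions))
        for k, r in enumerate(reactions):
            if r.order == 0:
                a[k] = cprop[k]
            elif r.order == 1:
                a[k] = cprop[k] * x[idx[r.educts[0]]]
            else:
                e1, e2 = r.educts
                if e1 == e2:
                    a[k] = cprop[k] * x[idx[e1]] * (x[idx[e1]] - 1) / 2.0
                else:
                    a[k] = cprop[k] * x[idx[e1]] * x[idx[e2]]
        a0 = a.sum()
        t_next = t + (rng.exponential(1.0 / a0) if a0 > 0 else math.inf)
        while rec < record_times.size and record_times[rec] <= min(t_next,
                                                                   t_end):
            out[rec] = x
            out_ev[rec] = ev
            rec += 1
        if t_next > t_end or a0 == 0:
            break
        t = t_next
        k = rng.choice(len(reactions), p=a / a0)
        x += stoich[k]
        ev[k] += 1
    while rec < record_times.size:
        out[rec] = x
        out_ev[rec] = ev
        rec += 1
    return ObservableSeries(record_times, names, out, np.zeros_like(out),
                            [r.name for r in reactions], out_ev)


def homogenized_cell_config(config: SimulationConfig, epsilon: float,
                            delta: float) -> SimulationConfig:
    """Obstacle-free surrogate of a crowded configuration.

    The cell volume is scaled by (1 - epsilon) so effective concentrations
    match the crowded cell, species diffusion is reset to delta*D0, and
    every bimolecular channel keeps the k_micro derived from the *in vitro*
    diffusion coefficient (via a kD_reference pin).  With epsilon = 0 and
    delta = 1 this is the identity transform (minus the obstacles).
    """
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must lie in [0, 1)")
    new = copy.deepcopy(config)
    R_new = config.geometry.cell_radius * (1.0 - epsilon) ** (1.0 / 3.0)
    new.geometry = CellGeometry(R_new)
    spmap = {s.name: s for s in config.species}
    new.species = [_replace_D(s, delta) for s in config.species]
    new_reactions = []
    for r in config.reactions:
        if r.kind == "bimolecular" and r.kD_reference is None:
            from dataclasses import replace
            a, b = spmap[r.educts[0]], spmap[r.educts[1]]
            kD_ref = collision_rate_kD(a.radius, b.radius, a.D0, b.D0)
            r = replace(r, kD_reference=kD_ref)
        new_reactions.append(r)
    new.reactions = new_reactions
    return new


def _replace_D(spec, delta):
    from dataclasses import replace
    return replace(spec, D0=spec.D0 * delta)
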