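"""Reaction machinery: rate conversions and per-step reaction operations.

The bimolecular scheme reacts any pair of educts whose centre distance is
below the physical collision radius ``R_crit = r_i + r_j`` with a
per-timestep probability ``P_react`` chosen so that in a well-mixed dilute
system the macroscopic mass-action rate ``k_macro`` is reproduced.  The
chain is:

    k_D      = 4*pi*(r_i+r_j)*(D_i+D_j)          (diffusion/collision limit)
    k_micro  = k_macro*k_D/(k_D - k_macro)       (per-collision reactivity)
    P_react  = k_micro*dt / V_collision,  V_collision = 4/3*pi*(r_i+r_j)^3

Bimolecular rate constants are given in L/(mol s); conversion between
molecules/um^3 and mol/L uses N_A/10^15.

The ``execute_*`` functions here are straightforward numpy implementations
of the individual per-step operations, acting on a
:class:`~crowdcell.dynamics.ParticleSystem`.  The production time loop in
:mod:`crowdcell.engine` fuses the same operations into a numba kernel; the
two routes are cross-checked in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

AVOGADRO = 6.02214076e23
#: (molecules per um^3) per (mol per litre)
CONC_FACTOR = AVOGADRO / 1.0e15

REACTION_KINDS = ("zero_order", "unimolecular", "bimolecular", "adsorption",
                  "dissociation", "membrane_influx", "membrane_export")


class DiffusionLimitError(ValueError):
    """Requested macroscopic rate at or above the collision limit k_D."""


class TimestepError(ValueError):
    """Timestep too large for a valid reaction probability."""


def collision_rate_kD(r_i: float, r_j: float, D_i: float, D_j: float) -> float:
    """Diffusion-limited (Smoluchowski) rate constant in L/(mol s).

    ``4*pi*(r_i+r_j)*(D_i+D_j)`` with radii in um and D in um^2/s, converted
    from um^3/s per molecule pair via N_A/10^15.
    """
    if r_i + r_j <= 0:
        raise ValueError("contact radius must be positive")
    if D_i + D_j <= 0:
        raise ValueError("combined diffusion coefficient must be positive")
    return 4.0 * math.pi * (r_i + r_j) * (D_i + D_j) * CONC_FACTOR


def micro_rate(k_macro: float, k_D: float) -> float:
    """Microscopic (per-collision) rate constant from the macroscopic one.

    Inverts ``1/k_macro = 1/k_micro + 1/k_D``; requires ``k_macro < k_D``
    (the simulation does not try to exceed the diffusion limit).
    """
    if k_macro < 0:
        raise ValueError("k_macro must be non-negative")
    if k_macro >= k_D:
        raise DiffusionLimitError(
            f"k_macro={k_macro:g} exceeds the diffusion limit k_D={k_D:g}")
    return k_macro * k_D / (k_D - k_macro)


def macro_rate(k_micro: float, k_D: float) -> float:
    """Macroscopic rate from microscopic and collision rates (Eq. inverse)."""
    return k_micro * k_D / (k_micro + k_D)


def reaction_probability(k_micro: float, dt: float, r_i: float,
                         r_j: float) -> float:
    """Per-step reaction probability for a pair inside the collision radius.

    ``P = k_micro*dt / V_collision`` with the collision volume
    ``4/3*pi*(r_i+r_j)^3``; ``k_micro`` in L/(mol s).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    v_coll = 4.0 / 3.0 * math.pi * (r_i + r_j) ** 3
    p = (k_micro / CONC_FACTOR) * dt / v_coll
    if p > 1.0:
        dt_max = v_coll / (k_micro / CONC_FACTOR)
        raise TimestepError(
            f"reaction probability {p:.3g} > 1; "
            f"maximal admissible dt is {dt_max:.3g} s")
    return p


def max_timestep(k_micro: float, r_i: float, r_j: float,
                 p_max: float = 1.0) -> float:
    """Largest dt giving P_react <= p_max for this channel."""
    v_coll = 4.0 / 3.0 * math.pi * (r_i + r_j) ** 3
    return p_max * v_coll / (k_micro / CONC_FACTOR)


def pogson_reaction_radius(k_macro: float, dt: float) -> float:
    """Reaction radius of the volume-wrapping scheme (legacy reference).

    ``R = (3*k*dt/(4*pi))**(1/3)`` with ``k_macro`` in L/(mol s) converted
    to um^3/s per molecule; grows with dt^(1/3).  Not used by the collision
    radius + probability scheme, provided for comparison.
    """
    if k_macro < 0:
        raise ValueError("k_macro must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    k_vol = k_macro / CONC_FACTOR
    return (3.0 * k_vol * dt / (4.0 * math.pi)) ** (1.0 / 3.0)


def kappa_from_bulk_rate(k_bind: float, accessible_volume: float,
                         surface_area: float) -> float:
    """Intrinsic surface velocity (um/s) for a target bulk binding rate.

    The adsorption layer of height ``kappa*dt`` with capture probability 1
    produces a first-order bulk rate ``kappa*A/V``; inverting gives
    ``kappa = k_bind*V/A``.
    """
    if surface_area <= 0:
        raise ValueError("surface_area must be positive")
    return k_bind * accessible_volume / surface_area


@dataclass(frozen=True)
class ReactionSpec:
    """One reaction channel.

    ``k_macro`` units depend on ``kind``: mol/(L s) for zero_order,
    1/s for unimolecular and dissociation, L/(mol s) for bimolecular,
    um/s (intrinsic surface velocity) for adsorption and membrane_export.
    ``molecules_per_s`` may replace ``k_macro`` for zero_order and
    membrane_influx sources.
    """

    kind: str
    educts: tuple = ()
    products: tuple = ()
    k_macro: float = 0.0
    molecules_per_s: float | None = None
    #: zero-order placement: "volume" or "membrane_shell"
    region: str = "volume"
    shell_thickness: float = 0.05
    #: adsorption targets
    bind_structures: bool = True
    bind_membrane: bool = False
    #: membrane export capture-layer height in um (defaults to kappa*dt)
    capture_layer: float | None = None
    #: override for the collision rate used to derive k_micro (used by the
    #: homogenized-cell transform where k_micro is fixed from in-vitro D)
    kD_reference: float | None = None
    name: str = ""

    def __post_init__(self):
        if self.kind not in REACTION_KINDS:
            raise ValueError(f"unknown reaction kind {self.kind!r}")
        if self.k_macro < 0:
            raise ValueError("rate constant must be non-negative")
        object.__setattr__(self, "educts", tuple(self.educts))
        object.__setattr__(self, "products", tuple(self.products))
        n_e = len(self.educts)
        arity = {"zero_order": 0, "unimolecular": 1, "bimolecular": 2,
                 "adsorption": 1, "dissociation": 1, "membrane_influx": 0,
                 "membrane_export": 1}[self.kind]
        if n_e != arity:
            raise ValueError(
                f"{self.kind} takes {arity} educts, got {n_e}")
        if self.kind in ("zero_order", "membrane_influx") \
                and len(self.products) != 1:
            raise ValueError(f"{self.kind} needs exactly one product")
        if self.kind == "bimolecular" and len(self.products) > 2:
            raise ValueError("at most two bimolecular products supported")
        if not self.name:
            lhs = "+".join(self.educts) or "0"
            rhs = "+".join(self.products) or "0"
            object.__setattr__(self, "name", f"{lhs}->{rhs}")


@dataclass(frozen=True)
class BimolecularKernel:
    """Derived per-channel parameters of the bimolecular scheme."""

    R_crit: float
    k_D: float
    k_micro: float
    P_react: float
    dt: float

    @classmethod
    def from_rates(cls, k_macro: float, r_i: float, r_j: float, D_i: float,
                   D_j: float, dt: float,
                   kD_reference: float | None = None) -> "BimolecularKernel":
        k_D = collision_rate_kD(r_i, r_j, D_i, D_j)
        k_ref = k_D if kD_reference is None else kD_reference
        k_mic = micro_rate(k_macro, k_ref)
        p = reaction_probability(k_mic, dt, r_i, r_j)
        return cls(R_crit=r_i + r_j, k_D=k_D, k_micro=k_mic, P_react=p,
                   dt=dt)

    def __post_init__(self):
        if not (0.0 <= self.P_react <= 1.0):
            raise ValueError("P_react must lie in (0, 1]")


# ---------------------------------------------------------------------------
# numpy reference implementations of the per-step operations
# ---------------------------------------------------------------------------

def execute_bimolecular(system, kernel: BimolecularKernel, spec: ReactionSpec,
                        rng: np.random.Generator):
    """One bimolecular sweep over a ParticleSystem; returns n_reactions.

    Candidate pairs (centre distance < R_crit) are visited in uniformly
    random order; each particle takes part in at most one reaction per step.
    Products replace educts in place; catalytic educts (present on both
    sides) are preserved unchanged.
    """
    e1, e2 = spec.educts
    i_ids = np.flatnonzero(system.alive & (system.species_name == e1))
    j_ids = np.flatnonzero(system.alive & (system.species_name == e2))
    if i_ids.size == 0 or j_ids.size == 0:
        return 0
    d = system.positions[i_ids, None, :] - system.positions[None, j_ids, :]
    close = np.sum(d * d, axis=2) < kernel.R_crit ** 2
    if e1 == e2:
        close &= i_ids[:, None] < j_ids[None, :]
    else:
        close &= i_ids[:, None] != j_ids[None, :]
    pairs = np.argwhere(close)
    if pairs.size == 0:
        return 0
    rng.shuffle(pairs, axis=0)
    pr1, pr2 = _bimolecular_product_slots(spec)
    used = set()
    n_react = 0
    for a, b in pairs:
        i, j = int(i_ids[a]), int(j_ids[b])
        if i in used or j in used:
            continue
        if rng.random() < kernel.P_react:
            used.add(i)
            used.add(j)
            n_react += 1
            for idx, prod in ((i, pr1), (j, pr2)):
                if prod is None:
                    system.alive[idx] = False
                elif prod != system.species_name[idx]:
                    system.set_species(idx, prod)
    return n_react


def _bimolecular_product_slots(spec: ReactionSpec):
    """Assign products to educt slots: catalytic educts keep themselves,
    remaining products go to the remaining educt slots in order (the first
    educt's position survives); unmatched educts are destroyed."""
    e1, e2 = spec.educts
    products = list(spec.products)
    slots = [None, None]
    for k, e in enumerate((e1, e2)):
        if e in products:
            slots[k] = e
            products.remove(e)
    for k in range(2):
        if slots[k] is None and products:
            slots[k] = products.pop(0)
    return slots[0], slots[1]


def execute_unimolecular(system, spec: ReactionSpec, dt: float,
                         rng: np.random.Generator,
                         warn_threshold: float = 0.1):
    """First-order conversion: each educt reacts with probability k*dt."""
    import warnings

    p = spec.k_macro * dt
    if p > warn_threshold:
        warnings.warn(f"k*dt = {p:.3g} > {warn_threshold}: first-order "
                      "discretization bias", stacklevel=2)
    ids = np.flatnonzero(system.alive & (system.species_name == spec.educts[0]))
    hit = ids[rng.random(ids.size) < p]
    products = list(spec.products)
    for idx in hit:
        if not products:
            system.alive[idx] = False
        else:
            system.set_species(idx, products[0])
            for extra in products[1:]:
                system.spawn(extra, system.positions[idx])
    return hit.size


def execute_zero_order(system, spec: ReactionSpec, geometry, dt: float,
                       rng: np.random.Generator):
    """Poisson creation, positions uniform over the accessible region."""
    if spec.molecules_per_s is not None:
        lam = spec.molecules_per_s * dt
    else:
        lam = spec.k_macro * CONC_FACTOR * geometry.cell_volume * dt
    n_new = rng.poisson(lam)
    name = spec.products[0]
    radius = system.species[name].radius
    R = geometry.cell_radius - radius
    for _ in range(n_new):
        for _try in range(2000):
            if spec.region == "membrane_shell":
                a = max(R - spec.shell_thickness, 0.0)
                rr = (a ** 3 + rng.random() * (R ** 3 - a ** 3)) ** (1 / 3)
                v = rng.standard_normal(3)
                p = v / np.linalg.norm(v) * rr
            else:
                p = (2.0 * rng.random(3) - 1.0) * R
                if p @ p > R * R:
                    continue
            if geometry.is_accessible(p, radius):
                system.spawn(name, p)
                break
        else:
            raise RuntimeError("zero-order placement saturated: geometry "
                               "too dense for rejection sampling")
    return n_new


def execute_adsorption(system, geometry, kappa_ads: float, dt: float,
                       rng: np.random.Generator, species=None,
                       bind_structures: bool = True,
                       bind_membrane: bool = False):
    """Bind unbound particles whose surface gap to a structure is < kappa*dt.

    Binding freezes the particle in place (mobility zero) without changing
    its species.  The layer height must stay well below the obstacle radii
    for the flat-layer volume argument to hold.
    """
    layer = kappa_ads * dt
    if layer <= 0:
        return 0
    radii = [r for r in
             list(geometry.cyl_r) + list(geometry.sph_r)]
    if bind_structures and radii and layer >= min(radii):
        raise ValueError("kappa_ads*dt must be far below the smallest "
                         "obstacle radius (flat-layer assumption)")
    sel = system.alive & ~system.bound
    if species is not None:
        sel &= system.species_name == species
    n_bound = 0
    for idx in np.flatnonzero(sel):
        p = system.positions[idx]
        radius = system.radius[idx]
        sep = math.inf
        if bind_structures:
            sep = _surface_separation(geometry, p, radius)
        if bind_membrane:
            sep = min(sep, geometry.cell_radius - np.linalg.norm(p) - radius)
        if sep < layer:
            system.bound[idx] = True
            n_bound += 1
    return n_bound


def _surface_separation(geometry, p, radius):
    sep = math.inf
    if geometry.n_cylinders:
        v = p - geometry.cyl_c
        t = np.clip(np.einsum("ij,ij->i", v, geometry.cyl_a),
                    -geometry.cyl_h, geometry.cyl_h)
        d = np.sqrt(np.sum((v - t[:, None] * geometry.cyl_a) ** 2, axis=1))
        sep = min(sep, float(np.min(d - geometry.cyl_r)) - radius)
    if geometry.n_spheres:
        d = np.sqrt(np.sum((p - geometry.sph_c) ** 2, axis=1))
        sep = min(sep, float(np.min(d - geometry.sph_r)) - radius)
    return sep


def execute_dissociation(system, k_diss: float, dt: float,
                         rng: np.random.Generator, species=None):
    """Unbind each bound particle with probability k_diss*dt."""
    p = k_diss * dt
    if p > 1.0:
        raise ValueError("k_diss*dt must not exceed 1")
    sel = system.alive & system.bound
    if species is not None:
        sel &= system.species_name == species
    ids = np.flatnonzero(sel)
    hit = ids[rng.random(ids.size) < p]
    system.bound[hit] = False
    return hit.size


def execute_membrane_export(system, geometry, spec: ReactionSpec, dt: float):
    """Remove export-species particles inside the membrane capture layer."""
    layer = (spec.capture_layer if spec.capture_layer is not None
             else spec.k_macro * dt)
    sel = system.alive & (system.species_name == spec.educts[0])
    ids = np.flatnonzero(sel)
    if ids.size == 0:
        return 0
    r = np.linalg.norm(system.positions[ids], axis=1)
    out = ids[r + system.radius[ids] > geometry.cell_radius - layer]
    system.alive[out] = False
    return out.size
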