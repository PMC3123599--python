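"""Preset experiments: test-model cells, transient binding, channeling.

The enzymatic test model creates substrate S at a zero-order rate k1 and
consumes it in S + E -> (P +) E with rate k2; the enzyme pool (2e-7 mol/L,
20,600 molecules at full scale) fixes the volume convention.  Presets can
be scaled down in two ways that leave the dimensionless physics (beta,
excluded fraction, obstacle microstructure) unchanged: fewer enzymes at the
same concentration (smaller volume) and a higher concentration scale
(shorter relaxation times).  The scale actually used is recorded in the
returned config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import SpeciesSpec
from .engine import ObservableSeries, SimulationConfig, run
from .geometry import (DEFAULT_DENSITY_MULTIPLIER, DEFAULT_CELL_RADIUS,
                       DEFAULT_CYL_LENGTH, DEFAULT_CYL_RADIUS, DEFAULT_N_CYLINDERS,
                       DEFAULT_N_SPHERES, DEFAULT_SPH_RADIUS,
                       TARGET_TRACER_EXCLUDED, TRACER_RADIUS, CellGeometry,
                       generate_geometry)
from .reactions import (CONC_FACTOR, ReactionSpec, collision_rate_kD,
                        kappa_from_bulk_rate, max_timestep, micro_rate)
from .reference import MassActionReaction, gillespie_run

# Test-model constants: enzyme pool and the three diffusion-limitation
# levels with their zero-order source rates (mol L^-1 s^-1) and bimolecular
# rate constants (L mol^-1 s^-1).
ENZYME_CONC = 2.0e-7
N_ENZYMES_FULL = 20_600
MOLECULE_RADIUS = 0.0025
D_FREE = 1.0
TEST_RATES = {
    0.01: (3.78e-9, 7.57e5),
    0.1: (3.78e-8, 7.57e6),
    0.3: (1.14e-7, 2.27e7),
}


def _default_dt(beta: float, k2: float, r_i: float, r_j: float,
                D_sum: float, p_max: float = 0.1) -> float:
    """Timestep bound: P_react <= p_max, and step length <= collision
    radius where diffusion limitation matters (beta >= 0.1)."""
    k_D = collision_rate_kD(r_i, r_j, D_sum / 2.0, D_sum / 2.0)
    k_mic = micro_rate(k2, k_D)
    dt = max_timestep(k_mic, r_i, r_j, p_max)
    if beta >= 0.095:  # nominally diffusion-limited regimes
        dt = min(dt, (r_i + r_j) ** 2 / (6.0 * D_sum))
    return dt


def model_cell_volume(n_enzymes: int, conc_scale: float = 1.0) -> float:
    """Cell volume (um^3) implied by the enzyme bookkeeping."""
    return n_enzymes / (ENZYME_CONC * conc_scale * CONC_FACTOR)


def preset_in_vitro(beta: float, n_enzymes: int = N_ENZYMES_FULL,
                    conc_scale: float = 1.0, seed: int = 0,
                    t_end: float | None = None,
                    track_product: bool = False,
                    geometry: CellGeometry | None = None) -> SimulationConfig:
    """Empty-cell enzymatic test model at diffusion limitation ``beta``.

    ``conc_scale`` multiplies all concentrations (k1 scales with its
    square so the steady-state count ratio S*/E is preserved);
    ``n_enzymes`` sets the volume.  The steady-state window starts after
    six relaxation times.
    """
    if beta not in TEST_RATES:
        raise ValueError(f"beta must be one of {sorted(TEST_RATES)}")
    k1, k2 = TEST_RATES[beta]
    k1 = k1 * conc_scale ** 2
    cE = ENZYME_CONC * conc_scale
    V = model_cell_volume(n_enzymes, conc_scale)
    R = (3.0 * V / (4.0 * math.pi)) ** (1.0 / 3.0)
    if geometry is None:
        geometry = CellGeometry(R)
    tau = 1.0 / (k2 * cE)
    if t_end is None:
        t_end = 30.0 * tau
    dt = _default_dt(beta, k2, MOLECULE_RADIUS, MOLECULE_RADIUS, 2 * D_FREE)
    dt = t_end / max(1, round(t_end / dt))
    species = [
        SpeciesSpec("E", MOLECULE_RADIUS, D_FREE, init_count=n_enzymes),
        SpeciesSpec("S", MOLECULE_RADIUS, D_FREE, init_count=0),
    ]
    products = ("E",)
    if track_product:
        species.append(SpeciesSpec("P", MOLECULE_RADIUS, D_FREE))
        products = ("P", "E")
    reactions = [
        ReactionSpec("zero_order", (), ("S",), k_macro=k1, name="birth"),
        ReactionSpec("bimolecular", ("S", "E"), products, k_macro=k2,
                     name="consume"),
    ]
    return SimulationConfig(
        geometry=geometry, species=species, reactions=reactions, dt=dt,
        t_end=t_end, seed=seed, observation_interval=max(tau / 15.0, dt),
        steady_state_window=(min(6.0 * tau, 0.5 * t_end), t_end))


def scaled_crowded_geometry(cell_radius: float, seed: int = 2011,
                            calibrate: bool = True,
                            target: float = TARGET_TRACER_EXCLUDED,
                            n_samples: int = 100_000) -> CellGeometry:
    """Crowded geometry for an arbitrary cell radius.

    Obstacle radii stay at their physical values; cylinder length and
    obstacle counts scale with the cell so the nominal volume fractions
    match the default cell.  The count multiplier is then re-calibrated so
    the 2.5 nm tracer-excluded fraction hits the 30.5 % operating point
    (membrane protrusion matters more in small cells).
    """
    ratio = cell_radius / DEFAULT_CELL_RADIUS
    cyl_len = DEFAULT_CYL_LENGTH * ratio
    n_cyl = DEFAULT_N_CYLINDERS * ratio ** 2  # volume ratio^3 / length ratio
    n_sph = DEFAULT_N_SPHERES * ratio ** 3

    def make(mult):
        return generate_geometry(cell_radius, int(round(n_cyl)), cyl_len,
                                 DEFAULT_CYL_RADIUS, int(round(n_sph)),
                                 DEFAULT_SPH_RADIUS, seed,
                                 density_multiplier=mult)

    mult = DEFAULT_DENSITY_MULTIPLIER
    if not calibrate:
        return make(mult)
    g = make(mult)
    f = g.sample_excluded_fraction(TRACER_RADIUS, n_samples, seed + 1).fraction
    m0, f0 = mult, f
    m1 = mult * 1.15
    for _ in range(8):
        if abs(f0 - target) <= 0.003:
            return make(m0)
        g = make(m1)
        f1 = g.sample_excluded_fraction(TRACER_RADIUS, n_samples,
                                        seed + 1).fraction
        if abs(f1 - f0) < 1e-6:
            break
        m0, f0, m1 = m1, f1, m1 + (target - f1) * (m1 - m0) / (f1 - f0)
        m1 = max(0.05, m1)
    return make(m0)


def preset_in_vivo(beta: float, n_enzymes: int = N_ENZYMES_FULL,
                   conc_scale: float = 1.0, seed: int = 0,
                   t_end: float | None = None, track_product: bool = False,
                   geometry: CellGeometry | None = None,
                   f_eff_estimate: float = 1.35) -> SimulationConfig:
    """Crowded-cell version of the test model (same rates and counts).

    The relaxation time shortens by roughly the effective-rate factor, so
    the steady-state window uses ``f_eff_estimate`` for its burn-in guess.
    """
    cfg = preset_in_vitro(beta, n_enzymes, conc_scale, seed, t_end,
                          track_product)
    if geometry is None:
        geometry = scaled_crowded_geometry(cfg.geometry.cell_radius,
                                           seed=seed + 2011)
    cfg.geometry = geometry
    k1, k2 = TEST_RATES[beta]
    tau = 1.0 / (f_eff_estimate * k2 * ENZYME_CONC * conc_scale)
    cfg.steady_state_window = (min(6.0 * tau, 0.5 * cfg.t_end), cfg.t_end)
    return cfg


def preset_binding(k_diss: float, target_fu: float,
                   geometry: CellGeometry,
                   tracer_radius: float = TRACER_RADIUS,
                   D0: float = D_FREE, n_tracers: int = 1000,
                   dt: float = 5.0e-6, t_end: float = 0.5,
                   seed: int = 0,
                   area_samples: int = 100_000) -> SimulationConfig:
    """Transient cytoskeleton binding tuned to a target unbound fraction.

    Chooses the intrinsic surface velocity kappa so the bulk binding rate
    ``k_bind = kappa*A/V`` satisfies ``fu = k_diss/(k_diss + k_bind)``; all
    tracers start unbound and fu(t) relaxes to the plateau.
    """
    if not 0 < target_fu <= 1:
        raise ValueError("target_fu must lie in (0, 1]")
    if target_fu < 1 and k_diss <= 0:
        raise ValueError("k_diss must be positive for target_fu < 1")
    if target_fu == 1.0:
        kappa = 0.0
    else:
        k_bind = k_diss * (1.0 - target_fu) / target_fu
        eps = geometry.sample_excluded_fraction(tracer_radius, area_samples,
                                               seed + 31).fraction
        V_acc = geometry.cell_volume * (1.0 - eps)
        A = geometry.effective_surface_area(tracer_radius, area_samples,
                                            seed + 32)
        kappa = kappa_from_bulk_rate(k_bind, V_acc, A)
    species = [SpeciesSpec("tracer", tracer_radius, D0,
                           init_count=n_tracers)]
    reactions = []
    if kappa > 0:
        reactions.append(ReactionSpec("adsorption", ("tracer",), (),
                                      k_macro=kappa, name="bind"))
        reactions.append(ReactionSpec("dissociation", ("tracer",), (),
                                      k_macro=k_diss, name="unbind"))
    return SimulationConfig(geometry=geometry, species=species,
                            reactions=reactions, dt=dt, t_end=t_end,
                            seed=seed,
                            observation_interval=max(t_end / 400, dt))


def measure_bimolecular_rate(k2: float, dt: float, seed: int,
                             geometry: CellGeometry | None = None,
                             n_enzymes: int = 1000,
                             conc_scale: float = 100.0,
                             n_substrate: int = 600,
                             t_end: float | None = None,
                             decay_factor: float = 5.0,
                             discard: float = 0.15,
                             kD_reference: float | None = None,
                             D0: float = D_FREE) -> dict:
    """Measure the effective bulk bimolecular rate from substrate decay.

    Runs S + E -> E with a constant enzyme pool (pseudo-first order in S):
    the substrate count decays as ``exp(-k_eff*c_E*t)``, so the slope of
    ``ln N_S`` against time over the post-transient window yields the
    effective macroscopic rate ``k_eff`` referred to the nominal enzyme
    concentration ``c_E = N_E/(V*N_A/1e15)``.  Returns a dict with
    ``k_eff``, the nominal ``c_E`` and the fit diagnostics.
    """
    from scipy import stats

    cE = ENZYME_CONC * conc_scale
    if geometry is None:
        V = model_cell_volume(n_enzymes, conc_scale)
        R = (3.0 * V / (4.0 * math.pi)) ** (1.0 / 3.0)
        geometry = CellGeometry(R)
    else:
        V = geometry.cell_volume
        cE = n_enzymes / (V * CONC_FACTOR)
    decay = k2 * cE
    if t_end is None:
        t_end = math.log(decay_factor) / decay * 1.3
    species = [
        SpeciesSpec("E", MOLECULE_RADIUS, D0, init_count=n_enzymes),
        SpeciesSpec("S", MOLECULE_RADIUS, D0, init_count=n_substrate),
    ]
    reactions = [ReactionSpec("bimolecular", ("S", "E"), ("E",), k_macro=k2,
                              kD_reference=kD_reference, name="consume")]
    cfg = SimulationConfig(geometry=geometry, species=species,
                           reactions=reactions, dt=dt, t_end=t_end,
                           seed=seed,
                           observation_interval=max(t_end / 200.0, dt))
    series = run(cfg)
    t = series.times
    n_s = series.count("S").astype(float)
    sel = (t >= discard * t_end) & (n_s > max(5, 0.02 * n_substrate))
    fit = stats.linregress(t[sel], np.log(n_s[sel]))
    return {"k_eff": -fit.slope / cE, "c_E": cE, "slope": fit.slope,
            "stderr": fit.stderr / cE, "series": series, "config": cfg}


# ---------------------------------------------------------------------------
# Metabolic channeling
# ---------------------------------------------------------------------------

LAYOUTS = ("channel_A", "layer_B", "random_C", "wellmixed_D")


@dataclass(frozen=True)
class ChannelLayout:
    """Spatial arrangement of the pathway enzymes.

    channel_A: co-localized ordered enzyme stacks under the membrane (each
    stack holds one enzyme of every pathway step, ordered inward in
    reaction order — an assembly line perpendicular to the membrane);
    layer_B: enzymes uniform in the membrane shell; random_C: uniform in
    the cell volume; wellmixed_D: no space at all (Gillespie reference).
    Enzymes are immobilized (D = 0) in A-C.
    """

    mode: str = "channel_A"
    shell_thickness: float = 0.05
    #: radial gap between consecutive enzymes of a stack (um)
    stack_spacing: float = 0.0075

    def __post_init__(self):
        if self.mode not in LAYOUTS:
            raise ValueError(f"mode must be one of {LAYOUTS}")


@dataclass
class ChannelingSetup:
    """A fully specified channeling experiment (spatial or well-mixed)."""

    layout: ChannelLayout
    config: SimulationConfig | None      # None for wellmixed_D
    ssa_reactions: list | None
    ssa_initial: dict | None
    volume: float
    t_end: float
    seed: int
    metabolites: tuple = ("M2", "M3", "M4", "M5")
    final_conversion: str = "M4+E4->M5+E4"

    def run(self) -> ObservableSeries:
        if self.layout.mode == "wellmixed_D":
            return gillespie_run(self.ssa_reactions, self.ssa_initial,
                                 self.volume, self.t_end, self.seed)
        return run(self.config)


def preset_channeling(layout: ChannelLayout | str,
                      D_metabolite: float = 1.0,
                      cell_radius: float = 2.5,
                      n_enzymes_each: int = 40_000,
                      influx_rate: float = 300.0,
                      k_cat: float = 3.78e6,
                      t_end: float = 1.6,
                      dt: float | None = None,
                      seed: int = 0) -> ChannelingSetup:
    """Membrane influx -> 3 enzymatic conversions -> membrane export.

    Metabolite 2 enters through the membrane shell, is converted by the
    immobilized enzymes E2 -> E4 into metabolites 3-5, and metabolite 5 is
    captured at the membrane (diffusion-controlled export, capture layer of
    one rms step).  All layouts share totals and rates so differences are
    attributable to enzyme placement only.  The well-mixed reference (D)
    uses a first-order export rate 15*D/R^2, the uniform-start mean
    first-passage rate to an absorbing sphere of the cell radius.
    """
    if isinstance(layout, str):
        layout = ChannelLayout(layout)
    if dt is None:
        kD = collision_rate_kD(MOLECULE_RADIUS, MOLECULE_RADIUS,
                               D_metabolite, 0.0)
        dt = _default_dt(k_cat / kD, k_cat, MOLECULE_RADIUS,
                         MOLECULE_RADIUS, D_metabolite)
        dt = min(dt, 8.0e-6)
    V = 4.0 / 3.0 * math.pi * cell_radius ** 3
    enzymes = ("E2", "E3", "E4")
    mets = ("M2", "M3", "M4", "M5")
    if layout.mode == "wellmixed_D":
        ssa = [MassActionReaction((), ("M2",),
                                  influx_rate / (CONC_FACTOR * V),
                                  name="influx")]
        for m_in, m_out, e in zip(mets[:-1], mets[1:], enzymes):
            ssa.append(MassActionReaction((m_in, e), (m_out, e), k_cat,
                                          name=f"{m_in}+{e}->{m_out}+{e}"))
        layer = math.sqrt(6.0 * D_metabolite * dt)
        kappa_exp = layer / dt
        area = 4.0 * math.pi * cell_radius ** 2
        ssa.append(MassActionReaction(("M5",), (), kappa_exp * area / V,
                                      name="export"))
        init = {e: n_enzymes_each for e in enzymes}
        init.update({m: 0 for m in mets})
        return ChannelingSetup(layout, None, ssa, init, V, t_end, seed)

    geometry = CellGeometry(cell_radius)
    species = []
    if layout.mode == "channel_A":
        rng = np.random.default_rng(seed + 77)
        dirs = rng.standard_normal((n_enzymes_each, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        depth0 = MOLECULE_RADIUS + 0.005  # first enzyme just under the membrane
    for k, e in enumerate(enzymes):
        if layout.mode == "channel_A":
            radial = cell_radius - depth0 - k * layout.stack_spacing
            species.append(SpeciesSpec(
                e, MOLECULE_RADIUS, 0.0, init_count=n_enzymes_each,
                init_distribution="fixed_positions",
                positions=dirs * radial))
        elif layout.mode == "layer_B":
            species.append(SpeciesSpec(
                e, MOLECULE_RADIUS, 0.0, init_count=n_enzymes_each,
                init_distribution="membrane_layer",
                shell_thickness=layout.shell_thickness))
        else:
            species.append(SpeciesSpec(
                e, MOLECULE_RADIUS, 0.0, init_count=n_enzymes_each))
    for m in mets:
        species.append(SpeciesSpec(m, MOLECULE_RADIUS, D_metabolite))
    reactions = [ReactionSpec("membrane_influx", (), ("M2",),
                              molecules_per_s=influx_rate,
                              shell_thickness=layout.shell_thickness,
                              name="influx")]
    for m_in, m_out, e in zip(mets[:-1], mets[1:], enzymes):
        reactions.append(ReactionSpec("bimolecular", (m_in, e), (m_out, e),
                                      k_macro=k_cat,
                                      name=f"{m_in}+{e}->{m_out}+{e}"))
    reactions.append(ReactionSpec(
        "membrane_export", ("M5",), (),
        capture_layer=math.sqrt(6.0 * D_metabolite * dt), name="export"))
    cfg = SimulationConfig(
        geometry=geometry, species=species, reactions=reactions, dt=dt,
        t_end=t_end, seed=seed, observation_interval=t_end / 200.0)
    return ChannelingSetup(layout, cfg, None, None, V, t_end, seed)


def product_formed(setup: ChannelingSetup, series: ObservableSeries,
                   at_time: float | None = None):
    """Cumulative metabolite-5 production (intracellular + exported),
    read from the event count of the final conversion channel."""
    values = series.event_count(setup.final_conversion).astype(float)
    if at_time is None:
        return series.times, values
    return float(np.interp(at_time, series.times, values))
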