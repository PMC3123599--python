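"""Engine: reproducibility, mass balance, steady-state statistics."""

import numpy as np
import pytest

from crowdcell.dynamics import SpeciesSpec
from crowdcell.engine import (ObservableSeries, SimulationConfig, run,
                              steady_state_average)
from crowdcell.geometry import CellGeometry
from crowdcell.reactions import ReactionSpec

R_MOL = 0.0025


def _birth_death_config(seed=0, n_enzymes=150, t_end=8.0):
    """Small birth-death test model: 0 -> S at k1, S + E -> E at k2."""
    from crowdcell.experiments import preset_in_vitro

    return preset_in_vitro(0.01, n_enzymes=n_enzymes, conc_scale=50.0,
                           seed=seed, t_end=t_end)


def test_config_validation(empty_cell):
    sp = [SpeciesSpec("A", R_MOL, 1.0, init_count=1)]
    with pytest.raises(ValueError):
        SimulationConfig(empty_cell, sp, dt=-1.0)
    with pytest.raises(ValueError):
        SimulationConfig(empty_cell, sp, dt=1e-3, t_end=1e-4)
    with pytest.raises(ValueError):
        SimulationConfig(empty_cell, sp, dt=1e-3, t_end=1.0,
                         observation_interval=1e-4)
    with pytest.raises(ValueError):
        SimulationConfig(empty_cell, sp, dt=1e-3, t_end=1.0,
                         steady_state_window=(0.5, 2.0))
    with pytest.raises(ValueError):
        SimulationConfig(empty_cell, sp + sp, dt=1e-3, t_end=1.0)


def test_timestep_guard_raised_before_run(empty_cell):
    """An over-large dt fails kernel validation before any stepping."""
    sp = [SpeciesSpec("A", R_MOL, 1.0, init_count=5),
          SpeciesSpec("B", R_MOL, 1.0, init_count=5)]
    rx = [ReactionSpec("bimolecular", ("A", "B"), (), k_macro=7.57e6)]
    cfg = SimulationConfig(empty_cell, sp, rx, dt=1.0, t_end=2.0)
    from crowdcell.reactions import TimestepError
    with pytest.raises(TimestepError):
        run(cfg)


def test_no_reactions_counts_constant(small_crowded):
    sp = [SpeciesSpec("A", R_MOL, 1.0, init_count=40)]
    cfg = SimulationConfig(small_crowded, sp, [], dt=1e-5, t_end=2e-3,
                           seed=1, observation_interval=1e-4)
    series = run(cfg)
    assert np.all(series.count("A") == 40)


def test_determinism_and_seed_sensitivity():
    cfg_a = _birth_death_config(seed=5, t_end=1.0)
    cfg_b = _birth_death_config(seed=5, t_end=1.0)
    cfg_c = _birth_death_config(seed=6, t_end=1.0)
    a, b, c = run(cfg_a), run(cfg_b), run(cfg_c)
    np.testing.assert_array_equal(a.counts, b.counts)
    np.testing.assert_array_equal(a.events, b.events)
    assert not np.array_equal(a.counts, c.counts)


def test_observation_interval_does_not_change_dynamics():
    cfg_fine = _birth_death_config(seed=2, t_end=0.5)
    cfg_coarse = _birth_death_config(seed=2, t_end=0.5)
    fine = run(cfg_fine)
    # double the realized interval so the coarse grid nests in the fine one
    cfg_coarse.observation_interval = 2 * float(fine.times[1])
    coarse = run(cfg_coarse)
    n = len(coarse.times)
    np.testing.assert_array_equal(fine.counts[::2][:n], coarse.counts)


def test_mass_balance_counts_vs_events():
    """Count changes are fully explained by the logged reaction events."""
    series = run(_birth_death_config(seed=3, t_end=1.0))
    births = series.event_count("birth")
    consumed = series.event_count("consume")
    n_s = series.count("S")
    np.testing.assert_array_equal(n_s, n_s[0] + births - consumed)
    assert np.all(series.count("E") == series.count("E")[0])


def test_birth_death_steady_state_matches_oracle():
    """Stationary mean and variance follow the linear birth-death chain.

    Oracle: with birth rate b and per-molecule death rate d the stationary
    distribution is Poisson with mean b/d, so sd ~ sqrt(mean).
    """
    cfg = _birth_death_config(seed=4, n_enzymes=150, t_end=8.0)
    series = run(cfg)
    mean, sd, se = steady_state_average(series, "S")
    predicted = 0.125 * 150  # steady state count from the rate construction
    assert mean == pytest.approx(predicted, abs=3 * se + 0.01 * predicted)
    assert sd == pytest.approx(np.sqrt(predicted), rel=0.4)


def test_steady_state_average_edges():
    times = np.linspace(0, 1, 50)
    counts = np.full((50, 1), 7)
    series = ObservableSeries(times, ["A"], counts, np.zeros_like(counts),
                              [], np.zeros((50, 0), np.int64))
    mean, sd, se = steady_state_average(series, "A", window=(0.2, 1.0))
    assert (mean, sd, se) == (7.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        steady_state_average(series, "A", window=(2.0, 3.0))
    with pytest.raises(ValueError):
        steady_state_average(series, "A")  # no window anywhere


def test_engine_matches_numpy_ops_statistically(empty_cell):
    """Fused kernel and the numpy per-step operations agree on a dilute
    bimolecular decay (same physics, independent implementations)."""
    from crowdcell.dynamics import ParticleSystem, diffusion_step
    from crowdcell.reactions import (BimolecularKernel, execute_bimolecular)

    k2 = 7.57e5
    sp = [SpeciesSpec("A", R_MOL, 1.0, init_count=150),
          SpeciesSpec("B", R_MOL, 1.0, init_count=150)]
    rx = [ReactionSpec("bimolecular", ("A", "B"), (), k_macro=k2)]
    geom = CellGeometry(0.15)
    dt, n_steps = 4e-5, 150
    cfg = SimulationConfig(geom, sp, rx, dt=dt, t_end=dt * n_steps, seed=8,
                           observation_interval=dt * n_steps)
    remaining_kernel = [run(cfg.__class__(**{**cfg.__dict__, "seed": s})
                            ).count("A")[-1] for s in range(8)]

    kern = BimolecularKernel.from_rates(k2, R_MOL, R_MOL, 1.0, 1.0, dt)
    remaining_numpy = []
    for s in range(8):
        rng = np.random.default_rng(s)
        system = ParticleSystem(sp, 400)
        system.place_initial(geom, rng)
        for _ in range(n_steps):
            diffusion_step(system, geom, dt, rng)
            execute_bimolecular(system, kern, rx[0], rng)
        remaining_numpy.append(system.count("A"))
    m_k, m_n = np.mean(remaining_kernel), np.mean(remaining_numpy)
    pooled_se = np.sqrt(np.var(remaining_kernel) / 8
                        + np.var(remaining_numpy) / 8)
    assert abs(m_k - m_n) < 3 * pooled_se + 1e-9
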