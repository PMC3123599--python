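"""Rate theory closed forms and the per-step reaction operations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowdcell.dynamics import ParticleSystem, SpeciesSpec
from crowdcell.geometry import CellGeometry
from crowdcell.reactions import (CONC_FACTOR, BimolecularKernel,
                                 DiffusionLimitError, ReactionSpec,
                                 TimestepError, collision_rate_kD,
                                 execute_adsorption, execute_bimolecular,
                                 execute_dissociation, execute_unimolecular,
                                 execute_zero_order, kappa_from_bulk_rate,
                                 macro_rate, micro_rate,
                                 pogson_reaction_radius,
                                 reaction_probability)

R_MOL = 0.0025  # 2.5 nm in um


class TestRateTheory:
    def test_collision_rate_values(self):
        # two equal 2.5 nm spheres at D = 1 um^2/s each
        # printed to three significant figures
        assert round(collision_rate_kD(R_MOL, R_MOL, 1.0, 1.0) / 1e7,
                     2) == 7.57
        # one partner immobilized: half the mobility, half the rate
        assert round(collision_rate_kD(R_MOL, R_MOL, 1.0, 0.0) / 1e7,
                     2) == 3.78

    def test_collision_rate_linearity_and_errors(self):
        base = collision_rate_kD(R_MOL, R_MOL, 1.0, 1.0)
        assert collision_rate_kD(2 * R_MOL, 2 * R_MOL, 1.0, 1.0) \
            == pytest.approx(2 * base)
        with pytest.raises(ValueError):
            collision_rate_kD(R_MOL, R_MOL, 0.0, 0.0)

    def test_micro_rate_fixed_points(self):
        kd = collision_rate_kD(R_MOL, R_MOL, 1.0, 1.0)
        assert micro_rate(0.0, kd) == 0.0
        assert micro_rate(0.5 * kd, kd) == pytest.approx(kd)
        assert micro_rate(0.3 * kd, kd) == pytest.approx(3.0 / 7.0 * kd)
        with pytest.raises(DiffusionLimitError):
            micro_rate(kd, kd)

    @settings(derandomize=True, max_examples=50)
    @given(frac=st.floats(0.0, 0.99))
    def test_micro_macro_roundtrip(self, frac):
        kd = collision_rate_kD(R_MOL, R_MOL, 1.0, 1.0)
        k = frac * kd
        assert macro_rate(micro_rate(k, kd), kd) == pytest.approx(
            k, rel=1e-12, abs=1e-9)

    def test_reaction_probability(self):
        kd = collision_rate_kD(R_MOL, R_MOL, 1.0, 1.0)
        km = micro_rate(7.57e5, kd)  # the 1 %-of-k_D test case
        p = reaction_probability(km, 1e-5, R_MOL, R_MOL)
        assert p == pytest.approx(0.0243, abs=5e-4)
        assert reaction_probability(km, 5e-6, R_MOL, R_MOL) \
            == pytest.approx(p / 2)
        assert reaction_probability(0.0, 1e-5, R_MOL, R_MOL) == 0.0
        with pytest.raises(TimestepError, match="admissible dt"):
            reaction_probability(km, 1.0, R_MOL, R_MOL)

    def test_pogson_radius(self):
        assert pogson_reaction_radius(0.0, 1e-5) == 0.0
        r1 = pogson_reaction_radius(1e6, 1e-5)
        assert pogson_reaction_radius(1e6, 8e-5) == pytest.approx(2 * r1)
        # unit case: k*dt = 4*pi/3 in volume units gives radius exactly 1
        k_unit = (4 * math.pi / 3) / 1e-5 * CONC_FACTOR
        assert pogson_reaction_radius(k_unit, 1e-5) == pytest.approx(1.0)

    def test_kernel_validation(self):
        kd = collision_rate_kD(R_MOL, R_MOL, 1.0, 1.0)
        kern = BimolecularKernel.from_rates(0.1 * kd, R_MOL, R_MOL, 1.0, 1.0,
                                            1e-6)
        assert kern.R_crit == pytest.approx(2 * R_MOL)
        assert 0 < kern.P_react <= 1
        with pytest.raises(DiffusionLimitError):
            BimolecularKernel.from_rates(1.1 * kd, R_MOL, R_MOL, 1.0, 1.0,
                                         1e-6)


class TestReactionSpec:
    def test_arity_checks(self):
        with pytest.raises(ValueError):
            ReactionSpec("bimolecular", ("A",), ("B",), 1.0)
        with pytest.raises(ValueError):
            ReactionSpec("unimolecular", (), ("B",), 1.0)
        with pytest.raises(ValueError):
            ReactionSpec("zero_order", (), (), 1.0)
        with pytest.raises(ValueError):
            ReactionSpec("nonsense", (), (), 1.0)
        r = ReactionSpec("bimolecular", ("S", "E"), ("P", "E"), 1.0)
        assert r.name == "S+E->P+E"


def _system(species, capacity=64):
    return ParticleSystem(species, capacity)


class TestPerStepOps:
    def test_bimolecular_trivia(self, empty_cell, rng):
        species = [SpeciesSpec("A", R_MOL, 1.0), SpeciesSpec("B", R_MOL, 1.0),
                   SpeciesSpec("C", R_MOL, 1.0)]
        spec = ReactionSpec("bimolecular", ("A", "B"), ("C",), 1.0)
        kern = BimolecularKernel(R_crit=2 * R_MOL, k_D=1.0, k_micro=1.0,
                                 P_react=1.0, dt=1e-6)
        sys = _system(species)
        sys.spawn("A", (0.0, 0.0, 0.0))
        sys.spawn("B", (0.1, 0.0, 0.0))  # far beyond R_crit
        assert execute_bimolecular(sys, kern, spec, rng) == 0
        sys = _system(species)
        sys.spawn("A", (0.0, 0.0, 0.0))
        sys.spawn("B", (0.003, 0.0, 0.0))  # inside R_crit, P = 1
        assert execute_bimolecular(sys, kern, spec, rng) == 1
        assert sys.count("C") == 1 and sys.count("A") == 0
        # product sits at the first educt's position
        c_idx = np.flatnonzero(sys.alive)[0]
        np.testing.assert_allclose(sys.positions[c_idx], 0.0)

    def test_bimolecular_one_reaction_per_particle(self, rng):
        """Two A near one B: B reacts with exactly one of them."""
        species = [SpeciesSpec("A", R_MOL, 1.0), SpeciesSpec("B", R_MOL, 1.0)]
        spec = ReactionSpec("bimolecular", ("A", "B"), (), 1.0)
        kern = BimolecularKernel(R_crit=2 * R_MOL, k_D=1.0, k_micro=1.0,
                                 P_react=1.0, dt=1e-6)
        sys = _system(species)
        sys.spawn("A", (0.001, 0.0, 0.0))
        sys.spawn("A", (-0.001, 0.0, 0.0))
        sys.spawn("B", (0.0, 0.0, 0.0))
        assert execute_bimolecular(sys, kern, spec, rng) == 1
        assert sys.count("A") == 1 and sys.count("B") == 0

    def test_bimolecular_catalysis_preserved(self, rng):
        species = [SpeciesSpec("S", R_MOL, 1.0), SpeciesSpec("E", R_MOL, 1.0),
                   SpeciesSpec("P", R_MOL, 1.0)]
        spec = ReactionSpec("bimolecular", ("S", "E"), ("P", "E"), 1.0)
        kern = BimolecularKernel(R_crit=2 * R_MOL, k_D=1.0, k_micro=1.0,
                                 P_react=1.0, dt=1e-6)
        sys = _system(species)
        sys.spawn("S", (0.0, 0.0, 0.0))
        e_idx = sys.spawn("E", (0.002, 0.0, 0.0))
        execute_bimolecular(sys, kern, spec, rng)
        assert sys.count("E") == 1 and sys.count("P") == 1
        assert sys.species_name[e_idx] == "E"  # catalyst untouched

    def test_unimolecular_decay_oracle(self, rng):
        """Survival after n steps matches (1-k dt)^n and exp(-k t)."""
        species = [SpeciesSpec("A", R_MOL, 1.0)]
        spec = ReactionSpec("unimolecular", ("A",), (), k_macro=100.0)
        sys = _system(species, capacity=4000)
        for _ in range(3000):
            sys.spawn("A", (0.0, 0.0, 0.0))
        dt, n_steps = 1e-4, 100  # k*dt = 0.01
        for _ in range(n_steps):
            execute_unimolecular(sys, spec, dt, rng)
        surv = sys.count("A") / 3000
        expected = math.exp(-100.0 * dt * n_steps)
        se = math.sqrt(expected * (1 - expected) / 3000)
        assert surv == pytest.approx(expected, abs=3 * se)

    def test_unimolecular_zero_rate_and_warning(self, rng):
        species = [SpeciesSpec("A", R_MOL, 1.0)]
        sys = _system(species)
        sys.spawn("A", (0, 0, 0))
        spec = ReactionSpec("unimolecular", ("A",), (), k_macro=0.0)
        assert execute_unimolecular(sys, spec, 1e-3, rng) == 0
        spec = ReactionSpec("unimolecular", ("A",), (), k_macro=1000.0)
        with pytest.warns(UserWarning, match="discretization"):
            execute_unimolecular(sys, spec, 1e-3, rng)

    def test_zero_order_poisson_and_accessibility(self, small_crowded, rng):
        species = [SpeciesSpec("S", R_MOL, 1.0)]
        sys = _system(species, capacity=20_000)
        k1 = 1e-8  # mol/(L s)
        dt = 1e-3
        lam = k1 * CONC_FACTOR * small_crowded.cell_volume * dt
        total = 0
        for _ in range(200):
            total += execute_zero_order(
                sys, ReactionSpec("zero_order", (), ("S",), k_macro=k1),
                small_crowded, dt, rng)
        expect = 200 * lam
        assert total == pytest.approx(expect, abs=3 * math.sqrt(expect))
        for i in range(sys.n_used):
            assert small_crowded.is_accessible(sys.positions[i], R_MOL)
        # zero rate creates nothing
        assert execute_zero_order(
            sys, ReactionSpec("zero_order", (), ("S",), k_macro=0.0),
            small_crowded, dt, rng) == 0

    def test_adsorption_flux_balance_oracle(self, rng):
        """Bulk binding rate approximates kappa * A_eff / V_accessible."""
        geom = CellGeometry(0.5, sph_c=[[0.0, 0.0, 0.0]], sph_r=[0.15])
        kappa, dt = 20.0, 1e-4
        species = [SpeciesSpec("T", R_MOL, 1.0, init_count=0)]
        sys = _system(species, capacity=6000)
        positions = []
        while len(positions) < 4000:
            p = rng.uniform(-0.5, 0.5, 3)
            if geom.is_accessible(p, R_MOL):
                positions.append(p)
        for p in positions:
            sys.spawn("T", p)
        bound = execute_adsorption(sys, geom, kappa, dt, rng)
        area = geom.effective_surface_area(R_MOL, 50_000, seed=1)
        eps = geom.sample_excluded_fraction(R_MOL, 50_000, seed=2).fraction
        v_acc = geom.cell_volume * (1 - eps)
        k_bind = kappa * area / v_acc
        expect = 4000 * k_bind * dt
        assert bound == pytest.approx(expect, abs=3 * math.sqrt(expect) + 2)
        # kappa = 0 binds nothing; far particles stay unbound
        assert execute_adsorption(sys, geom, 0.0, dt, rng) == 0

    def test_adsorption_layer_guard(self, rng):
        geom = CellGeometry(0.5, sph_c=[[0.0, 0.0, 0.0]], sph_r=[0.01])
        sys = _system([SpeciesSpec("T", R_MOL, 1.0)])
        with pytest.raises(ValueError, match="obstacle radius"):
            execute_adsorption(sys, geom, kappa_ads=200.0, dt=1e-3, rng=rng)

    def test_dissociation_lifetime(self, rng):
        species = [SpeciesSpec("T", R_MOL, 1.0)]
        sys = _system(species, capacity=3000)
        for _ in range(2000):
            sys.spawn("T", (0, 0, 0), bound=True)
        k_diss, dt = 50.0, 1e-4
        steps_alive = np.zeros(0)
        lifetimes = []
        for step in range(1, 4000):
            before = sys.bound.copy()
            execute_dissociation(sys, k_diss, dt, rng)
            released = before & ~sys.bound & sys.alive
            lifetimes += [step * dt] * int(released.sum())
            if not sys.bound.any():
                break
        mean_life = np.mean(lifetimes)
        se = 1.0 / k_diss / math.sqrt(len(lifetimes))
        assert mean_life == pytest.approx(1.0 / k_diss, abs=3 * se + dt)
        with pytest.raises(ValueError):
            execute_dissociation(sys, 1e6, 1.0, rng)

    def test_kappa_from_bulk_rate(self):
        assert kappa_from_bulk_rate(10.0, 100.0, 500.0) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            kappa_from_bulk_rate(1.0, 1.0, 0.0)
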