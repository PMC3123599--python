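"""Crowding-correction calculus, ODE steady states, Gillespie reference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowdcell.reactions import CONC_FACTOR, collision_rate_kD, micro_rate
from crowdcell.reference import (CrowdingFactors, MassActionReaction, f_diff,
                                 f_vol, gillespie_run,
                                 homogenized_cell_config, ode_steady_state)


class TestFactors:
    def test_f_vol_values(self):
        assert f_vol(0.0) == 1.0
        assert f_vol(0.5) == 2.0
        assert round(f_vol(0.305), 2) == 1.44
        with pytest.raises(ValueError):
            f_vol(1.0)

    def test_f_diff_values(self):
        assert f_diff(0.5, 1.0) == 1.0
        assert round(f_diff(0.1, 0.77), 2) == 0.97
        assert f_diff(0.3, 0.77) == pytest.approx(0.918, abs=5e-4)
        with pytest.raises(ValueError):
            f_diff(1.0, 0.5)
        with pytest.raises(ValueError):
            f_diff(0.1, 0.0)

    def test_f_eff_bundle(self):
        fac = CrowdingFactors(0.305, 0.1, 0.77, f_access=0.966)
        assert round(fac.f_eff, 2) == 1.35
        assert fac.f_eff == fac.f_vol * fac.f_diff * fac.f_access
        trivial = CrowdingFactors(0.0, 0.0, 1.0, 1.0)
        assert trivial.f_eff == 1.0
        keys = set(fac.as_dict())
        assert {"epsilon", "beta", "delta", "f_vol", "f_diff", "f_access",
                "f_eff"} <= keys

    @settings(derandomize=True, max_examples=60)
    @given(beta=st.floats(0.0, 0.95), delta=st.floats(0.05, 1.0))
    def test_f_diff_equals_rate_chain(self, beta, delta):
        """f_diff must equal the explicit chain: fix k_micro from (k, k_D),
        scale k_D by delta, recompose the effective macroscopic rate."""
        kD = collision_rate_kD(0.0025, 0.0025, 1.0, 1.0)
        k = beta * kD
        k_mic = micro_rate(k, kD)
        kD_eff = delta * kD
        k_eff = k_mic * kD_eff / (k_mic + kD_eff)
        assert f_diff(beta, delta) == pytest.approx(
            k_eff / k if k > 0 else 1.0, rel=1e-10)

    @settings(derandomize=True, max_examples=40)
    @given(eps=st.floats(0.0, 0.9), beta=st.floats(0.0, 0.9),
           delta=st.floats(0.05, 1.0), fa=st.floats(0.1, 1.0))
    def test_in_vivo_prediction_is_in_vitro_over_f_eff(self, eps, beta,
                                                       delta, fa):
        fac = CrowdingFactors(eps, beta, delta, fa)
        c_vitro, n_vitro = ode_steady_state(3.78e-9, 7.57e5, 2e-7, 1000)
        c_vivo, n_vivo = ode_steady_state(3.78e-9, 7.57e5, 2e-7, 1000,
                                          f_eff=fac.f_eff)
        assert c_vivo == pytest.approx(c_vitro / fac.f_eff, rel=1e-12)
        assert n_vivo == pytest.approx(n_vitro / fac.f_eff, rel=1e-12)


class TestOdeSteadyState:
    def test_reference_rates_count(self):
        # k1/(k2 cE) with the printed rate constants and 20,600 enzymes
        c_s, count = ode_steady_state(3.78e-9, 7.57e5, 2e-7, 20_600)
        assert count == pytest.approx(2575, rel=0.002)
        assert c_s == pytest.approx(3.78e-9 / (7.57e5 * 2e-7))

    def test_linearity_and_errors(self):
        c1, n1 = ode_steady_state(1e-9, 7.57e5, 2e-7, 100)
        c2, n2 = ode_steady_state(2e-9, 7.57e5, 2e-7, 100)
        assert c2 == pytest.approx(2 * c1) and n2 == pytest.approx(2 * n1)
        assert ode_steady_state(0.0, 7.57e5, 2e-7)[0] == 0.0
        with pytest.raises(ValueError):
            ode_steady_state(1e-9, 0.0, 2e-7)


class TestGillespie:
    def test_no_reactions_constant(self):
        series = gillespie_run([], {"A": 17}, volume=1.0, t_end=1.0, seed=0)
        assert np.all(series.count("A") == 17)

    def test_same_seed_identical(self):
        rx = [MassActionReaction((), ("A",), 1e-8),
              MassActionReaction(("A",), (), 5.0)]
        a = gillespie_run(rx, {"A": 0}, 1.0, 5.0, seed=3)
        b = gillespie_run(rx, {"A": 0}, 1.0, 5.0, seed=3)
        c = gillespie_run(rx, {"A": 0}, 1.0, 5.0, seed=4)
        np.testing.assert_array_equal(a.counts, b.counts)
        assert not np.array_equal(a.counts, c.counts)

    def test_birth_death_stationary_moments(self):
        """Linear birth-death chain: stationary distribution is Poisson.

        Oracle: birth propensity b, death rate d per molecule -> mean b/d,
        variance b/d.
        """
        V = 1.0
        b_conc = 4e-8  # mol/(L s) -> b = 24.1 molecules/s in 1 um^3
        d = 2.0
        rx = [MassActionReaction((), ("A",), b_conc),
              MassActionReaction(("A",), (), d)]
        times = np.linspace(0, 200, 2000)
        series = gillespie_run(rx, {"A": 0}, V, 200.0, seed=9,
                               record_times=times)
        x = series.count("A")[200:]
        mean_exp = b_conc * CONC_FACTOR * V / d
        n_indep = 190  # ~decorrelation time 1/d = 0.5 s, samples 0.1 s apart
        se = np.sqrt(mean_exp / n_indep) * 2
        assert x.mean() == pytest.approx(mean_exp, abs=3 * se)
        assert x.var() == pytest.approx(mean_exp, rel=0.35)

    def test_enzymatic_model_matches_ode(self):
        """SSA stationary mean of the test model reproduces k1/(k2 cE)."""
        n_e = 500
        V = n_e / (2e-7 * CONC_FACTOR) * 1e-2  # concentration scale x100
        cE = n_e / (V * CONC_FACTOR)
        k1 = 3.78e-9 * 1e4
        k2 = 7.57e5
        rx = [MassActionReaction((), ("S",), k1),
              MassActionReaction(("S", "E"), ("E",), k2)]
        tau = 1.0 / (k2 * cE)
        times = np.linspace(0, 30 * tau, 1500)
        series = gillespie_run(rx, {"S": 0, "E": n_e}, V, 30 * tau, seed=11,
                               record_times=times)
        x = series.count("S")[500:]
        pred = ode_steady_state(k1, k2, cE, n_e)[1]
        se = np.sqrt(pred / (20 * tau / tau)) * 1.5
        assert x.mean() == pytest.approx(pred, abs=3 * se)


class TestHomogenized:
    def _config(self):
        from crowdcell.experiments import preset_in_vitro
        return preset_in_vitro(0.1, n_enzymes=200, conc_scale=50.0, seed=0)

    def test_identity_transform(self):
        cfg = self._config()
        out = homogenized_cell_config(cfg, 0.0, 1.0)
        assert out.geometry.cell_radius == pytest.approx(
            cfg.geometry.cell_radius)
        assert [s.D0 for s in out.species] == [s.D0 for s in cfg.species]

    def test_volume_and_diffusion_scaling(self):
        cfg = self._config()
        out = homogenized_cell_config(cfg, 0.305, 0.77)
        assert out.geometry.cell_volume == pytest.approx(
            0.695 * cfg.geometry.cell_volume)
        assert out.species[0].D0 == pytest.approx(0.77 * cfg.species[0].D0)
        # k_micro is pinned to the in-vitro collision rate
        r = next(x for x in out.reactions if x.kind == "bimolecular")
        kD_vitro = collision_rate_kD(0.0025, 0.0025, 1.0, 1.0)
        assert r.kD_reference == pytest.approx(kD_vitro)
        kern = out.bimolecular_kernels()[r.name]
        assert kern.k_micro == pytest.approx(micro_rate(r.k_macro, kD_vitro))
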