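"""Obstacle world: accessibility queries, index correctness, MC sampling."""

import math

import numpy as np
import pytest

from crowdcell.geometry import (CellGeometry, Cylinder, SphereObstacle,
                                VolumeSample, build_spatial_index,
                                generate_geometry)


def test_domain_type_validation():
    with pytest.raises(ValueError):
        Cylinder((0, 0, 0), (1, 0, 0), length=-1.0, radius=0.1)
    with pytest.raises(ValueError):
        Cylinder((0, 0, 0), (2, 0, 0), length=1.0, radius=0.1)  # not unit
    with pytest.raises(ValueError):
        SphereObstacle((0, 0, 0), radius=0.0)
    with pytest.raises(ValueError):
        VolumeSample(1.5, 0.0, 10, 0)
    with pytest.raises(ValueError):
        CellGeometry(-1.0)
    with pytest.raises(ValueError):
        generate_geometry(1.0, 10, -0.5, 0.02, 0, 0.0, seed=0)


def test_empty_geometry_trivia(empty_cell):
    assert empty_cell.is_accessible((0, 0, 0), 0.5)
    assert not empty_cell.is_accessible((0, 0, 1.2), 0.01)  # outside the cell
    vs = empty_cell.sample_excluded_fraction(0.001, 2000, seed=0)
    assert vs.fraction == 0.0
    fa = empty_cell.sample_access_factor(0.01, 0.01, 50, 20, seed=0)
    assert fa.fraction == 1.0


def test_generation_determinism_and_counts():
    a = generate_geometry(1.0, 30, 0.5, 0.02, 40, 0.03, seed=7)
    b = generate_geometry(1.0, 30, 0.5, 0.02, 40, 0.03, seed=7)
    c = generate_geometry(1.0, 30, 0.5, 0.02, 40, 0.03, seed=8)
    np.testing.assert_array_equal(a.cyl_c, b.cyl_c)
    np.testing.assert_array_equal(a.sph_c, b.sph_c)
    assert not np.array_equal(a.cyl_c, c.cyl_c)
    assert a.n_cylinders == 30 and a.n_spheres == 40
    half = generate_geometry(1.0, 30, 0.5, 0.02, 40, 0.03, seed=7,
                             density_multiplier=0.5)
    assert half.n_cylinders == 15 and half.n_spheres == 20
    # centres are drawn inside the cell ball, so every obstacle meets it
    assert np.all(np.linalg.norm(a.cyl_c, axis=1) <= a.cell_radius)
    assert np.all(np.linalg.norm(a.sph_c, axis=1) <= a.cell_radius)


def test_cylinder_boundary_case():
    geom = CellGeometry(1.0, cyl_c=[[0.0, 0.0, 0.0]], cyl_a=[[0.0, 0.0, 1.0]],
                        cyl_len=[1.0], cyl_r=[0.05])
    probe = 0.01
    inside = (0.05 + probe) * (1 - 1e-6)
    outside = (0.05 + probe) * (1 + 1e-6)
    assert not geom.is_accessible((inside, 0.0, 0.0), probe)
    assert geom.is_accessible((outside, 0.0, 0.0), probe)
    # beyond the capsule end the segment distance governs
    assert geom.is_accessible((0.0, 0.0, 0.58), probe)


def test_index_matches_bruteforce(small_crowded, rng):
    """Grid-indexed accessibility must agree with the all-obstacle scan."""
    pts = rng.uniform(-0.85, 0.85, size=(10_000, 3))
    probes = rng.uniform(0.0, 0.009, size=10_000)
    mismatch = sum(
        small_crowded.is_accessible(p, pr)
        != small_crowded.is_accessible_bruteforce(p, pr)
        for p, pr in zip(pts, probes))
    assert mismatch == 0


def test_index_query_superset(small_crowded, rng):
    """Every obstacle within reach of a point is registered at its cell."""
    build_spatial_index(small_crowded)
    g = small_crowded
    for p in rng.uniform(-0.7, 0.7, size=(300, 3)):
        hits = set(g.index.query(p))
        v = p - g.cyl_c
        t = np.clip(np.einsum("ij,ij->i", v, g.cyl_a), -g.cyl_h, g.cyl_h)
        d_cyl = np.sqrt(np.sum((v - t[:, None] * g.cyl_a) ** 2, axis=1))
        d_sph = np.sqrt(np.sum((p - g.sph_c) ** 2, axis=1))
        for i in np.flatnonzero(d_cyl < g.cyl_r + g.reach):
            assert i in hits
        for i in np.flatnonzero(d_sph < g.sph_r + g.reach):
            assert i + g.n_cylinders in hits


def test_excluded_fraction_analytic_and_monotone():
    # single centred obstacle sphere: fraction = (a/R)^3 for a point probe
    geom = CellGeometry(1.0, sph_c=[[0.0, 0.0, 0.0]], sph_r=[0.4])
    vs = geom.sample_excluded_fraction(0.0, 50_000, seed=3)
    assert vs.fraction == pytest.approx(0.4 ** 3, abs=3 * vs.standard_error)
    fractions = [geom.sample_excluded_fraction(p, 20_000, seed=5).fraction
                 for p in (0.0, 0.05, 0.1, 0.2)]
    assert all(b >= a for a, b in zip(fractions, fractions[1:]))


def test_excluded_fraction_dilute_additive():
    """Non-overlapping dilute spheres: measured = summed volume / cell."""
    rng = np.random.default_rng(9)
    centers = rng.uniform(-0.5, 0.5, size=(20, 3))
    geom = CellGeometry(1.0, sph_c=centers, sph_r=np.full(20, 0.03))
    vs = geom.sample_excluded_fraction(0.0, 200_000, seed=4)
    analytic = 20 * 0.03 ** 3  # ratio of summed to cell volume
    assert vs.fraction == pytest.approx(analytic,
                                        abs=3 * vs.standard_error + 1e-4)


def test_access_factor_bounds_and_far_wall(small_crowded):
    fa = small_crowded.sample_access_factor(0.0025, 0.0025, 400, 50, seed=6)
    assert 0.0 <= fa.fraction <= 1.0
    # a single distant obstacle leaves the interaction volume untouched
    # (up to the thin membrane shell where the interaction ball protrudes)
    geom = CellGeometry(2.0, sph_c=[[0.0, 0.0, 1.9]], sph_r=[0.05])
    fa = geom.sample_access_factor(0.002, 0.002, 200, 30, seed=7)
    assert fa.fraction == pytest.approx(1.0, abs=0.005)


def test_access_saturation_error():
    # cell fully plugged by one big sphere: no accessible centres exist
    geom = CellGeometry(0.5, sph_c=[[0.0, 0.0, 0.0]], sph_r=[0.6])
    with pytest.raises(RuntimeError, match="satur"):
        geom.sample_access_factor(0.01, 0.01, 10, 10, seed=0, max_tries=50)


def test_csv_roundtrip(tmp_path, small_crowded):
    path = tmp_path / "geom.csv"
    small_crowded.save_csv(path)
    back = CellGeometry.load_csv(path)
    assert back.cell_radius == small_crowded.cell_radius
    np.testing.assert_array_equal(back.cyl_c, small_crowded.cyl_c)
    np.testing.assert_array_equal(back.cyl_a, small_crowded.cyl_a)
    np.testing.assert_array_equal(back.cyl_r, small_crowded.cyl_r)
    np.testing.assert_array_equal(back.sph_c, small_crowded.sph_c)
    np.testing.assert_array_equal(back.sph_r, small_crowded.sph_r)


def test_effective_surface_area_sphere():
    """A single interior sphere: accessible area equals its full surface."""
    geom = CellGeometry(1.0, sph_c=[[0.0, 0.0, 0.0]], sph_r=[0.2])
    area = geom.effective_surface_area(0.005, 20_000, seed=8)
    assert area == pytest.approx(4 * math.pi * 0.2 ** 2, rel=0.02)
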