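"""CG potential terms, surface field, and Langevin integrator behaviour."""

import numpy as np
import pytest
from dataclasses import replace

from quasi2d import fixtures as fx
from quasi2d.structure import Molecule
from quasi2d.energy import (
    ATTRACTIVE,
    KB,
    REPULSIVE,
    CGParams,
    CGSystem,
    Restraints,
    Schedule,
    SurfaceField,
    build_surface,
    langevin_run,
    surface_energy,
    total_energy,
)


def single_bead(z):
    return Molecule(["CA"], ["C"], [[0.0, 0.0, z]], ["A"], [1], ["ALA"])


def isolated_field(eps=-1.0, mode=ATTRACTIVE):
    return SurfaceField(np.array([[0.0, 0.0, 0.0]]), r_min=5.0, epsilon=eps, mode=mode)


class TestSurfaceConstruction:
    def test_default_grid_has_625_beads(self):
        fld = build_surface(125.0, 125.0, 25)
        assert len(fld.bead_positions) == 625

    def test_two_per_side_gives_corners(self):
        fld = build_surface(10.0, 10.0, 2)
        xy = sorted(map(tuple, fld.bead_positions[:, :2]))
        assert xy == [(-5.0, -5.0), (-5.0, 5.0), (5.0, -5.0), (5.0, 5.0)]

    def test_default_spacing(self):
        fld = build_surface(125.0, 125.0, 25)
        xs = np.unique(fld.bead_positions[:, 0])
        assert np.diff(xs)[0] == pytest.approx(125.0 / 24.0)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            build_surface(-1.0, 10.0, 5)
        with pytest.raises(ValueError):
            build_surface(10.0, 10.0, 1)


class TestSurfaceEnergy:
    def test_minimum_at_rmin_equals_epsilon(self):
        assert surface_energy(single_bead(5.0), isolated_field()) == pytest.approx(-1.0)

    def test_far_away_is_zero(self):
        assert surface_energy(single_bead(500.0), isolated_field()) == 0.0

    def test_tail_value_matches_formula(self):
        # |eps| * ((rmin/r)^12 - 2 (rmin/r)^6) at r = 2 rmin
        expected = 1.0 * (2.0**-12 - 2.0 * 2.0**-6)
        got = surface_energy(single_bead(10.0), isolated_field())
        assert got == pytest.approx(expected)

    def test_attractive_mode_nonpositive_everywhere(self):
        fld = isolated_field()
        for z in np.linspace(0.5, 11.9, 40):
            assert surface_energy(single_bead(z), fld) <= 0.0

    def test_repulsive_mode_nonnegative_and_zero_beyond_rmin(self):
        fld = isolated_field(eps=1.0, mode=REPULSIVE)
        for z in np.linspace(1.0, 4.9, 20):
            assert surface_energy(single_bead(z), fld) >= 0.0
        assert surface_energy(single_bead(5.1), fld) == 0.0

    def test_epsilon_sign_validated(self):
        with pytest.raises(ValueError):
            SurfaceField(np.zeros((1, 3)), epsilon=+1.0, mode=ATTRACTIVE)


class TestSchedule:
    def test_monotone_deepening_enforced(self):
        with pytest.raises(ValueError):
            Schedule(epsilon_steps=(-1.0, -0.5))
        Schedule(epsilon_steps=(-0.5, -1.0, -3.0, -6.0, -9.0))


class TestTotalEnergy:
    def test_ideal_geometry_has_zero_bonded_terms(self):
        m = fx.make_beta_strand(6)
        _, br = total_energy(m, params=CGParams(attr_epsilon=0.0))
        assert br["bond"] == pytest.approx(0.0, abs=1e-6)
        assert br["angle"] == pytest.approx(0.0, abs=1e-4)
        assert br["excluded_volume"] >= 0.0

    def test_bond_compression_is_harmonic(self):
        m = fx.make_beta_strand(4)
        params = CGParams(attr_epsilon=0.0)
        e0, _ = total_energy(m, params=params)
        # compress the first N-CA bond by 0.1 Å
        i = m.atom_index("A", 1, "N")
        j = m.atom_index("A", 1, "CA")
        d = m.coords[j] - m.coords[i]
        m2 = m.copy()
        m2.coords[i] += 0.1 * d / np.linalg.norm(d)
        e1, _ = total_energy(m2, params=params)
        assert e1 - e0 == pytest.approx(params.bond_k * 0.01, rel=1e-3)

    def test_breakdown_sums_to_total(self, insulin_like):
        tot, br = total_energy(insulin_like)
        assert tot == pytest.approx(sum(br.values()), rel=1e-12)

    def test_matches_brute_force_pairwise_sum(self):
        """Nonbonded terms equal an independent per-pair python loop."""
        rng = np.random.default_rng(0)
        m = fx.make_beta_strand(8)
        m.coords = m.coords + rng.normal(0, 0.3, m.coords.shape)
        p = CGParams()
        system = CGSystem(m, p)
        br, _ = system.energy_forces(m.coords)
        e_ev = e_at = 0.0
        for i, j, sig in zip(system.nb_i, system.nb_j, system.nb_sigma):
            r = float(np.linalg.norm(m.coords[i] - m.coords[j]))
            if r < sig:
                x6 = (sig / r) ** 6
                e_ev += p.ev_epsilon * (x6**2 - 2 * x6 + 1)
            if r < p.attr_rmin:
                e_at -= p.attr_epsilon
            elif r < p.cutoff:
                x6 = (p.attr_rmin / r) ** 6
                lj = p.attr_epsilon * (x6**2 - 2 * x6)
                t = np.clip((r - p.switch_start) / (p.cutoff - p.switch_start), 0, 1)
                s = 1 - (10 * t**3 - 15 * t**4 + 6 * t**5)
                e_at += lj * s
        assert br["excluded_volume"] == pytest.approx(e_ev, rel=1e-10)
        assert br["attraction"] == pytest.approx(e_at, rel=1e-10)


class TestForces:
    def test_forces_match_finite_differences(self):
        """Analytic forces agree with central differences on a randomly
        perturbed chain with field and restraints active."""
        rng = np.random.default_rng(3)
        m = fx.make_beta_strand(6)
        m.disulfides = [(("A", 1), ("A", 5))]
        m.res_names[:] = "CYS"
        params = CGParams()
        system = CGSystem(m, params)
        fld = build_surface(40.0, 40.0, 5, plane_offset=-8.0, epsilon=-2.0)
        rst = Restraints()
        rst.add_pair(1, 21, 6.0, 3.0, flat_bottom=True)
        rst.add_dihedral((2, 5, 6, 7), -100.0, 5.0)
        rst.add_tether(0, [0.3, 0.3, 0.3], 2.0)
        x0 = m.coords + rng.normal(0, 0.2, m.coords.shape)
        _, f = system.energy_forces(x0, [fld], rst)
        h = 1e-5
        for _ in range(30):
            a = rng.integers(0, len(x0))
            d = rng.integers(0, 3)
            xp = x0.copy()
            xp[a, d] += h
            xm = x0.copy()
            xm[a, d] -= h
            ep = sum(system.energy_forces(xp, [fld], rst)[0].values())
            em = sum(system.energy_forces(xm, [fld], rst)[0].values())
            fd = -(ep - em) / (2 * h)
            assert f[a, d] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestLangevin:
    def test_zero_temperature_ideal_geometry_static(self):
        m = fx.make_beta_strand(5)
        params = CGParams(temperature=0.0, attr_epsilon=0.0)
        x, _ = langevin_run(m, [], params, 300, seed=1)
        assert np.abs(x - m.coords).max() < 1e-9

    def test_same_seed_reproduces_trajectory(self, insulin_like):
        params = CGParams()
        xa, ta = langevin_run(insulin_like, [], params, 150, seed=7)
        xb, tb = langevin_run(insulin_like, [], params, 150, seed=7)
        assert np.array_equal(xa, xb)
        assert np.array_equal(ta.frames, tb.frames)

    def test_different_seed_differs(self, insulin_like):
        params = CGParams()
        xa, _ = langevin_run(insulin_like, [], params, 100, seed=7)
        xb, _ = langevin_run(insulin_like, [], params, 100, seed=8)
        assert not np.allclose(xa, xb)

    def test_tethered_bead_samples_boltzmann_variance(self):
        """A harmonically tethered bead's positional variance matches the
        thermostat's stationary distribution within 10%."""
        m = single_bead(0.0)
        k = 5.0
        params = CGParams(temperature=300.0, attr_epsilon=0.0, friction=0.02)
        rst = Restraints()
        rst.add_tether(0, [0.0, 0.0, 0.0], k)
        system = CGSystem(m, params)
        x = m.coords.copy()
        samples = []
        _, traj = langevin_run(
            system, [], params, 60000, seed=12, restraints=rst, coords=x, stride=10
        )
        pos = traj.frames[200:, 0, :]
        var = pos.var(axis=0).mean()
        # E = k x^2 per dof -> var = kB T / (2 k)
        expected = KB * 300.0 / (2 * k)
        assert var == pytest.approx(expected, rel=0.10)

    def test_divergence_detected(self):
        m = single_bead(0.0)
        m2 = single_bead(3.0)
        bad = Molecule(
            ["CA", "CA"], ["C", "C"], [[0, 0, 0], [0, 0, 1e-4]], ["A", "A"], [1, 2], ["ALA"] * 2
        )
        from quasi2d.energy import DivergenceError

        # overlapping excluded-volume beads at huge timestep blow up
        params = CGParams(temperature=0.0, timestep=2000.0, friction=1e-6)
        rst = Restraints()
        rst.add_pair(0, 1, 50.0, 1000.0)
        with pytest.raises(DivergenceError):
            langevin_run(bad, [], params, 2000, seed=0, restraints=rst)


class TestSurfaceBinding:
    def test_deeper_epsilon_binds_closer(self):
        """Mean height above the surface decreases monotonically over the
        deepening epsilon schedule."""
        m = fx.make_beta_strand(5)
        m = m.transformed(translation=[0, 0, 6.0 - m.coords[:, 2].min()])
        params = CGParams(temperature=300.0)
        fld = build_surface(60.0, 60.0, 13)
        heights = []
        x = m.coords.copy()
        system = CGSystem(m, params)
        for eps in (-0.5, -1.0, -3.0, -6.0, -9.0):
            x, traj = langevin_run(
                system, [fld.with_epsilon(eps)], params, 2500, seed=4, coords=x, stride=50
            )
            tail = traj.frames[-20:]
            heights.append(float(np.mean([f[:, 2].mean() for f in tail])))
        assert all(b < a + 0.4 for a, b in zip(heights[:-1], heights[1:]))
        assert heights[-1] < heights[0]
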