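"""Squashing protocol, flatness QC, plate relaxation, dihedral scoring."""

import numpy as np
import pytest

from quasi2d import fixtures as fx
from quasi2d.structure import Molecule
from quasi2d.energy import CGParams, Schedule, build_surface, total_energy
from quasi2d._geometry import rotation_about_axis
from quasi2d.planarize import (
    PlanarConformer,
    extended_score,
    flatness_qc,
    orientation_set,
    planarize,
    relax_between_plates,
    run_campaign,
)


class TestOrientations:
    def test_six_proper_rotations(self):
        rots = orientation_set()
        assert len(rots) == 6
        for r in rots:
            assert np.linalg.det(r) == pytest.approx(1.0)
            assert np.allclose(r @ r.T, np.eye(3), atol=1e-12)

    def test_orientations_distinct(self):
        rots = orientation_set()
        for i in range(6):
            for j in range(i + 1, 6):
                assert not np.allclose(rots[i], rots[j])


class TestFlatnessQC:
    def test_flat_bead_sheet_passes(self):
        xs, ys = np.meshgrid(np.arange(5) * 3.8, [0.0, 6.0])
        pts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(10)])
        m = Molecule(
            ["CA"] * 10, ["C"] * 10, pts,
            ["A"] * 5 + ["B"] * 5, list(range(1, 6)) * 2, ["ALA"] * 10,
        )
        conf = PlanarConformer.from_molecule(m)
        assert conf.qc_pass
        assert conf.thickness == pytest.approx(0.0, abs=1e-9)

    def test_folded_over_terminus_fails_with_crossing(self, fc3_conformer):
        """A terminus folded back over the loop at 5 Å normal separation is
        rejected as a projected segment crossing."""
        mol = fc3_conformer.molecule.copy()
        # fold A1..A3 over the core: place them above interior residues
        for rid, (x, y) in zip((1, 2, 3), ((10.0, 2.0), (13.5, 2.0), (17.0, 2.0))):
            for name in ("N", "CA", "C", "O", "SC"):
                if mol.has_atom("A", rid, name):
                    i = mol.atom_index("A", rid, name)
                    mol.coords[i] = [x, y, 5.0]
        report = flatness_qc(PlanarConformer.from_molecule(mol, run_qc=False))
        assert not report.passed
        assert report.n_crossings > 0

    def test_thick_conformer_fails(self, insulin_like):
        report = flatness_qc(PlanarConformer.from_molecule(insulin_like, run_qc=False))
        assert not report.passed
        assert report.thickness > 8.0

    def test_verdict_invariant_under_rigid_motion(self, fc3_conformer):
        rot = rotation_about_axis([1.0, 0.7, 0.1], 2.1)
        moved = fc3_conformer.molecule.transformed(rotation=rot, translation=[4, 4, -9])
        report = flatness_qc(PlanarConformer.from_molecule(moved, run_qc=False))
        assert report.passed == fc3_conformer.qc_pass
        assert report.thickness == pytest.approx(fc3_conformer.thickness, abs=1e-6)


class TestExtendedScore:
    def test_beta_strand_scores_one(self):
        assert extended_score(fx.make_beta_strand(10)) == 1.0

    def test_alpha_helix_scores_zero(self):
        assert extended_score(fx.make_alpha_helix(10)) == 0.0

    def test_mixed_chain_direct_count(self):
        """12 residues, 6 extended among the 10 non-terminal -> 0.6."""
        phi_psi = [(-120.0, 130.0)] * 7 + [(-57.0, -47.0)] * 5
        m = fx.make_chain(phi_psi)
        # non-terminal residues: 2..11; residues 2..7 extended (6 of 10)
        assert extended_score(m) == pytest.approx(0.6)

    def test_too_few_residues_rejected(self):
        with pytest.raises(ValueError):
            extended_score(fx.make_beta_strand(2))

    def test_invariant_under_rigid_motion(self, fc3_conformer):
        rot = rotation_about_axis([0.1, 0.9, 0.4], 0.9)
        moved = fc3_conformer.molecule.transformed(rotation=rot, translation=[1, 2, 3])
        assert extended_score(moved) == pytest.approx(extended_score(fc3_conformer))


class TestPlanarize:
    @pytest.fixture(scope="class")
    def short_runs(self, insulin_like):
        field = build_surface(70.0, 70.0, 15)
        params = CGParams(friction=0.01)
        schedule = Schedule(steps_per_stage=700)
        out = []
        for seed in range(3):
            monitors, conf = planarize(
                insulin_like, orientation_set()[seed], field, schedule, params, seed=seed
            )
            out.append((monitors, conf))
        return out

    def test_thickness_decreases(self, short_runs):
        for monitors, conf in short_runs:
            assert conf.thickness < monitors.thickness.iloc[0]

    def test_radius_of_gyration_grows_on_flattening(self, short_runs, insulin_like):
        from quasi2d._geometry import radius_of_gyration

        rg0 = radius_of_gyration(insulin_like.coords)
        grew = sum(conf.rg > rg0 - 0.3 for _, conf in short_runs)
        assert grew >= 2

    def test_monitors_track_schedule(self, short_runs):
        monitors, _ = short_runs[0]
        assert list(monitors.columns) == [
            "time_fs", "epsilon", "rg", "z_com", "z_max", "thickness",
        ]
        assert sorted(monitors.epsilon.unique()) == [-9.0, -6.0, -3.0, -1.0, -0.5]

    def test_disulfides_survive_the_squash(self, short_runs):
        for _, conf in short_runs:
            mol = conf.molecule
            for (c1, r1), (c2, r2) in mol.disulfides:
                d = np.linalg.norm(
                    mol.coords[mol.atom_index(c1, r1, "SC")]
                    - mol.coords[mol.atom_index(c2, r2, "SC")]
                )
                assert abs(d - 2.04) / 2.04 < 0.10

    def test_same_seed_reproducible(self, insulin_like):
        field = build_surface(50.0, 50.0, 11)
        params = CGParams(friction=0.01)
        schedule = Schedule(steps_per_stage=80)
        rot = orientation_set()[1]
        _, c1 = planarize(insulin_like, rot, field, schedule, params, seed=9)
        _, c2 = planarize(insulin_like, rot, field, schedule, params, seed=9)
        assert np.array_equal(c1.molecule.coords, c2.molecule.coords)


class TestRelaxBetweenPlates:
    def test_relaxation_reduces_bonded_strain(self, fc3_conformer):
        params = CGParams(temperature=100.0)
        _, br0 = total_energy(fc3_conformer.molecule)
        relaxed = relax_between_plates(fc3_conformer, params, n_steps=300, seed=1)
        _, br1 = total_energy(relaxed.molecule)
        assert br1["bond"] + br1["angle"] <= 1.05 * (br0["bond"] + br0["angle"])
        assert relaxed.thickness <= 15.0

    def test_topology_class_preserved(self, fc1_conformer):
        from quasi2d import topology as topo

        params = CGParams(temperature=100.0)
        relaxed = relax_between_plates(fc1_conformer, params, n_steps=300, seed=2)
        assert topo.classify(relaxed).label == "FC1"

    def test_re_relaxation_is_near_fixed_point_for_strain(self, fc3_conformer):
        """The bonded strain the relaxation exists to remove is gone after
        one pass: a second pass changes it by under 1% of the total."""
        params = CGParams(temperature=0.0)
        once = relax_between_plates(fc3_conformer, params, n_steps=0, seed=0)
        _, br1 = total_energy(once.molecule)
        again = relax_between_plates(once, params, n_steps=0, seed=0)
        _, br2 = total_energy(again.molecule)
        s1 = br1["bond"] + br1["angle"] + br1["disulfide"]
        s2 = br2["bond"] + br2["angle"] + br2["disulfide"]
        assert abs(s2 - s1) <= 0.01 * (abs(s1) + abs(s2)) + 0.3


class TestCampaign:
    def test_bookkeeping(self, insulin_like):
        field = build_surface(50.0, 50.0, 11)
        params = CGParams(friction=0.01)
        schedule = Schedule(steps_per_stage=60)
        result = run_campaign(
            insulin_like, field, schedule, params, n_runs_per_orientation=2, seed=3
        )
        assert len(result.runs) == 12
        assert set(result.runs.orientation.unique()) == set(range(6))
        assert result.runs.seed.nunique() == 12
        ab = result.abundance_table()
        if len(ab):
            assert ab.percent.sum() == pytest.approx(100.0)

    def test_success_rates_table(self, insulin_like):
        field = build_surface(50.0, 50.0, 11)
        params = CGParams(friction=0.01)
        schedule = Schedule(steps_per_stage=40)
        result = run_campaign(
            insulin_like, field, schedule, params, n_runs_per_orientation=1, seed=4
        )
        rates = result.success_rates()
        assert rates.n_runs.sum() == 6
        assert ((0 <= rates.success_rate) & (rates.success_rate <= 1)).all()
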