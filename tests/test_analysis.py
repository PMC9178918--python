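"""Fibril metrics: twist, pitch, RMSD, beta content, boxes, cavities."""

import math

import numpy as np
import pytest

from quasi2d import fixtures as fx
from quasi2d.structure import Molecule
from quasi2d.stack import ProtofilamentModel
from quasi2d._geometry import rotation_about_axis
from quasi2d.analysis import (
    AnchorError,
    AnchorSet,
    beta_content,
    bounding_box,
    contact_map,
    core_rmsd,
    count_cavity_waters,
    find_cavities,
    hydrate_cavity,
    pitch,
    twist,
)


class TestTwist:
    def test_pure_translation_stack_is_untwisted(self, fc3_conformer):
        m = fx.make_twisted_stack(fc3_conformer, 4, 0.0, 4.95)
        assert twist(m) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("t", [-5.0, -0.9, -0.1, 0.37, 2.5, 5.0])
    def test_constructed_twist_recovered(self, fc3_conformer, t):
        m = fx.make_twisted_stack(fc3_conformer, 10, t, 4.95)
        assert twist(m) == pytest.approx(t, abs=0.01)

    def test_invariant_under_global_rigid_motion(self, fc3_conformer):
        m = fx.make_twisted_stack(fc3_conformer, 5, -0.9, 4.95)
        t0 = twist(m)
        rot = rotation_about_axis([1.0, 0.4, -0.2], 0.8)
        moved = ProtofilamentModel(
            [lay.transformed(rotation=rot, translation=[10, -3, 6]) for lay in m.layers]
        )
        # transformed() rotates each layer about its own centroid; rebuild
        # the stack with one common rotation instead
        layers = []
        for lay in m.layers:
            c = lay.copy()
            c.coords = lay.coords @ rot.T + np.array([10.0, -3.0, 6.0])
            layers.append(c)
        assert twist(ProtofilamentModel(layers)) == pytest.approx(t0, abs=1e-6)

    def test_missing_anchor_atoms_reported(self, fc3_conformer):
        m = fx.make_twisted_stack(fc3_conformer, 3, 0.0, 4.95)
        anchors = AnchorSet(
            pair1=(("A", 7, "SC"), ("A", 20, "SC")),
            pair2=(("B", 7, "SC"), ("Z", 1, "SC")),
        )
        with pytest.raises(AnchorError, match="Z"):
            twist(m, anchors)


class TestPitch:
    def test_fc3_value(self):
        assert pitch(0.9, 4.95) == pytest.approx(198.0)
        assert pitch(-0.9, 4.95) == pytest.approx(198.0)

    def test_fc1_value(self):
        assert pitch(0.1, 4.95) == pytest.approx(1782.0)

    def test_half_turn(self):
        assert pitch(180.0, 4.95) == pytest.approx(0.99)

    def test_zero_twist_unbounded(self):
        assert math.isinf(pitch(0.0, 4.95))

    def test_invalid_rise(self):
        with pytest.raises(ValueError):
            pitch(1.0, -1.0)

    def test_consistency_with_constructed_stack(self, fc3_conformer):
        """pitch(twist(m), rise(m)) equals the construction's pitch to 1%."""
        for t, r in ((-0.9, 4.95), (1.1, 4.5), (-2.0, 5.2)):
            m = fx.make_twisted_stack(fc3_conformer, 8, t, r)
            expected = (360.0 / abs(t)) * r / 10.0
            assert pitch(twist(m), m.rise()) == pytest.approx(expected, rel=0.01)


class TestCoreRmsd:
    def test_identity_is_zero(self, insulin_like):
        assert core_rmsd(insulin_like, insulin_like) == pytest.approx(0.0, abs=1e-9)

    def test_translation_superposed_away(self, insulin_like):
        moved = insulin_like.transformed(translation=[5.0, 0.0, 0.0])
        assert core_rmsd(moved, insulin_like) == pytest.approx(0.0, abs=1e-9)

    def test_uses_27_core_residues(self, insulin_like):
        from quasi2d.analysis import core_selection

        assert len(core_selection(insulin_like)) == 27

    def test_matches_rotation_grid_oracle_on_toy(self):
        """Optimal-superposition RMSD of a 4-point toy matches a brute
        rotation-search oracle to 1e-3 Å."""
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(5)
        a = rng.normal(0, 2.0, (4, 3))
        b = a + rng.normal(0, 0.5, (4, 3))
        ma = Molecule(["CA"] * 4, ["C"] * 4, a, ["A"] * 4, [1, 2, 3, 4], ["ALA"] * 4)
        mb = Molecule(["CA"] * 4, ["C"] * 4, b, ["A"] * 4, [1, 2, 3, 4], ["ALA"] * 4)
        got = core_rmsd(ma, mb)

        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)

        def obj(euler):
            r = Rotation.from_euler("xyz", euler).as_matrix()
            return np.sqrt((((ac @ r.T) - bc) ** 2).sum(axis=1).mean())

        best = np.inf
        for e0 in np.linspace(-np.pi, np.pi, 7):
            for e1 in np.linspace(-np.pi / 2, np.pi / 2, 5):
                for e2 in np.linspace(-np.pi, np.pi, 7):
                    res = minimize(obj, [e0, e1, e2], method="Nelder-Mead")
                    best = min(best, res.fun)
        assert got == pytest.approx(best, abs=1e-3)

    def test_selection_mismatch_raises(self, insulin_like):
        short = fx.make_beta_strand(5)
        with pytest.raises(ValueError):
            core_rmsd(short, insulin_like)


class TestBetaContent:
    def test_two_layer_beta_stack_fully_beta_over_chain(self):
        strand = fx.make_beta_strand(8)
        m = fx.make_twisted_stack(strand, 2, 0.0, 4.8)
        bc = beta_content(m)
        # non-terminal residues are all beta; termini lack dihedrals
        core = bc.per_residue.iloc[1:-1]
        assert (core == 1.0).all()
        assert not bc.dihedral_only

    def test_helix_has_zero_beta(self):
        helix = fx.make_alpha_helix(8)
        m = fx.make_twisted_stack(helix, 2, 0.0, 5.0)
        assert beta_content(m).fraction == 0.0

    def test_single_layer_flagged_dihedral_only(self):
        bc = beta_content(fx.make_beta_strand(8))
        assert bc.dihedral_only

    def test_monotone_in_layer_count(self, fc3_conformer):
        fracs = [
            beta_content(fx.make_twisted_stack(fc3_conformer, n, 0.0, 4.8)).fraction
            for n in (2, 3, 4)
        ]
        assert fracs[0] <= fracs[1] + 1e-12 <= fracs[2] + 2e-12


class TestBoundingBox:
    def test_unit_cube_regardless_of_orientation(self):
        corners = np.array(
            [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
        )
        rot = rotation_about_axis([1.0, 1.0, 0.3], 0.7)
        pts = corners @ rot.T + 5.0
        m = Molecule(
            ["CA"] * 8, ["C"] * 8, pts, ["A"] * 8, list(range(1, 9)), ["ALA"] * 8
        )
        w, h = bounding_box(m)
        assert w == pytest.approx(1.0, abs=1e-3)
        assert h == pytest.approx(1.0, abs=1e-3)

    def test_loop_regime_smaller_with_protruding_termini(self, fc3_conformer):
        mol = fc3_conformer.molecule
        wa, _ = bounding_box(mol, "all_atoms")
        wl, _ = bounding_box(mol, "loop_only")
        assert wl < wa

    def test_invariance_under_rigid_motion(self, fc3_conformer):
        mol = fc3_conformer.molecule
        w0, h0 = bounding_box(mol)
        rot = rotation_about_axis([0.2, 1.0, 0.5], 1.3)
        moved = mol.transformed(rotation=rot, translation=[7, -2, 3])
        w1, h1 = bounding_box(moved)
        assert w1 == pytest.approx(w0, abs=0.05)
        assert h1 == pytest.approx(h0, abs=0.05)

    def test_unknown_regime_rejected(self, fc3_conformer):
        with pytest.raises(ValueError):
            bounding_box(fc3_conformer.molecule, "everything")


class TestContactMap:
    def test_symmetric(self, fc3_conformer):
        maps = contact_map(fx.make_twisted_stack(fc3_conformer, 3, 0.0, 4.8))
        for key in ("intra", "inter"):
            mat = maps[key].to_numpy()
            assert np.allclose(mat, mat.T)

    def test_extended_chain_only_near_diagonal(self):
        strand = fx.make_beta_strand(12)
        intra = contact_map(strand, cutoff=8.0)["intra"].to_numpy()
        i, j = np.nonzero(intra)
        assert np.abs(i - j).max() <= 2

    def test_fc3_interchain_band_spans_both_chains(self, fc3_conformer):
        """The all-termini-outside topology aligns the A- and B-chains
        along their whole lengths: the interchain block of the contact
        map carries an off-diagonal band."""
        intra = contact_map(fc3_conformer.molecule, cutoff=8.0)["intra"]
        a_labels = [f"A{r}" for r in range(7, 21)]
        b_labels = [f"B{r}" for r in range(7, 20)]
        block = intra.loc[a_labels, b_labels].to_numpy()
        touched = block.sum(axis=1) > 0
        # the band covers most of the core and spans its full length
        assert touched.mean() >= 0.8
        third = len(touched) // 3
        assert touched[:third].any()
        assert touched[third : 2 * third].any()
        assert touched[2 * third :].any()


def hollow_tube_model(inner_radius=6.0, n_rings=5, ring_spacing=3.0):
    """Capped tube of CA beads enclosing a cylindrical channel."""
    coords = []
    for k in range(n_rings):
        z = k * ring_spacing
        for ang in np.linspace(0, 2 * np.pi, 18, endpoint=False):
            coords.append([inner_radius * np.cos(ang), inner_radius * np.sin(ang), z])
    # caps
    for z in (-ring_spacing, n_rings * ring_spacing):
        for r in (0.0, 2.0, 4.0, 6.0):
            n = max(1, int(2 * np.pi * r / 2.0))
            for ang in np.linspace(0, 2 * np.pi, n, endpoint=False):
                coords.append([r * np.cos(ang), r * np.sin(ang), z])
    coords = np.array(coords)
    n = len(coords)
    return Molecule(
        ["CA"] * n, ["C"] * n, coords, ["A"] * n, list(range(1, n + 1)), ["ALA"] * n
    )


class TestCavities:
    def test_solid_slab_has_no_cavities(self):
        xs, ys = np.meshgrid(np.arange(6) * 2.0, np.arange(6) * 2.0)
        pts = []
        for z in (0.0, 2.0, 4.0):
            pts.append(np.column_stack([xs.ravel(), ys.ravel(), np.full(36, z)]))
        pts = np.concatenate(pts)
        n = len(pts)
        slab = Molecule(["CA"] * n, ["C"] * n, pts, ["A"] * n, list(range(1, n + 1)), ["ALA"] * n)
        assert find_cavities(slab).n_cavities == 0

    def test_capped_tube_has_one_spanning_cavity(self):
        tube = hollow_tube_model()
        cav = find_cavities(tube)
        assert cav.n_cavities == 1
        z = cav.voxel_centers[0][:, 2]
        assert z.max() - z.min() > 6.0  # spans several rings

    def test_origin_shift_robustness(self):
        tube = hollow_tube_model()
        v0 = len(find_cavities(tube).voxel_centers[0])
        shifted = tube.transformed(translation=[0.37, 0.61, 0.23])
        cavs = find_cavities(shifted)
        assert cavs.n_cavities == 1
        v1 = len(cavs.voxel_centers[0])
        assert abs(v1 - v0) / v0 < 0.35  # within ~a voxel shell


class TestCavityWaters:
    def test_dry_model_counts_zero(self):
        tube = hollow_tube_model()
        cav = find_cavities(tube)
        per, n, had = count_cavity_waters(ProtofilamentModel([tube]), cav)
        assert (per, n, had) == (0.0, 0, False)

    def test_placed_channel_waters_per_monomer(self, fc3_conformer):
        tube = hollow_tube_model()
        cav = find_cavities(tube)
        model = ProtofilamentModel([tube] * 4)
        model.water_coords = np.array([[0.0, 0.0, 1.0 + k] for k in range(8)])
        per, n, had = count_cavity_waters(model, cav)
        assert had and n == 8
        assert per == pytest.approx(2.0)

    def test_matches_brute_force_pair_scan(self):
        """The KD-tree implementation equals a plain all-pairs python scan
        (shell and in-voxel routes alike)."""
        tube = hollow_tube_model()
        cav = find_cavities(tube)
        rng = np.random.default_rng(0)
        waters = rng.uniform(-8, 8, (40, 3))
        model = ProtofilamentModel([tube])
        model.water_coords = waters
        per, n, had = count_cavity_waters(model, cav)
        wall_pts = cav.atom_coords[cav.wall_atom_indices[0]]
        vox = cav.voxel_centers[0]
        by_shell = {
            i for i, w in enumerate(waters)
            if np.any(np.linalg.norm(wall_pts - w, axis=1) < 2.5)
        }
        by_voxel = {
            i for i, w in enumerate(waters)
            if np.any(np.linalg.norm(vox - w, axis=1) < 0.87)
        }
        expected = by_voxel if len(by_voxel) > len(by_shell) else by_shell
        assert n == len(expected)


class TestHydration:
    def test_zero_cavity_model_unchanged(self):
        strand = fx.make_beta_strand(6)
        cav = find_cavities(strand)
        out = hydrate_cavity(strand, cav)
        assert len(out.water_coords) == 0

    def test_hydration_idempotent(self):
        tube = hollow_tube_model()
        cav = find_cavities(tube)
        once = hydrate_cavity(tube, cav)
        n1 = len(once.water_coords)
        assert n1 > 0
        twice = hydrate_cavity(once, cav)
        assert len(twice.water_coords) == n1

    def test_packing_count_tracks_volume(self):
        tube = hollow_tube_model()
        cav = find_cavities(tube)
        volume = cav.volumes()[0]
        n = len(hydrate_cavity(tube, cav).water_coords)
        assert n == pytest.approx(volume / 30.0, abs=2.0)
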