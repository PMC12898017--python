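"""Topology/trajectory I/O, unwrapping and stability metrics."""

from __future__ import annotations

import numpy as np
import pytest

from paraperm.errors import (
    FormatError,
    InsufficientDataError,
    ParseError,
    SelectionError,
    ShapeError,
)
from paraperm.traj import (
    Frame,
    Topology,
    Trajectory,
    backbone_selection,
    ion_selection,
    read_frames,
    read_topology,
    rmsd_timeseries,
    rmsf_per_residue,
    select,
    unwrap_coordinates,
    write_native,
    write_topology,
)

from conftest import ion_atom, make_frame, make_traj, protein_atom, rigid_transform

TOY_PDB = """\
CRYST1  100.000  100.000  100.000  90.00  90.00  90.00 P 1           1
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.300   1.200   0.000  1.00  0.00           C
END
"""

TWO_CHAIN_PDB = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY B   1       0.000   5.000   0.000  1.00  0.00           C
END
"""


class TestReadTopology:
    def test_toy_pdb_counts(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(TOY_PDB)
        top, frame = read_topology(p)
        assert top.n_atoms == 3
        assert len(top.residue_index) == 1
        assert frame.coords.shape == (3, 3)
        assert np.allclose(frame.box_lengths, 100.0)

    def test_two_chains_residue_index(self, tmp_path):
        p = tmp_path / "two.pdb"
        p.write_text(TWO_CHAIN_PDB)
        top, _ = read_topology(p)
        assert set(top.residue_index) == {("A", 1), ("A", 2), ("B", 1)}

    def test_truncated_coordinate_raises_with_line_number(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM      1  N   GLY A   1       0.000   0.0\n")
        with pytest.raises(ParseError, match="line 1"):
            read_topology(p)

    def test_pdb_round_trip(self, tmp_path):
        top = Topology(
            [protein_atom(1, "CA", 7, "ALA", "B", element="C"), ion_atom(2, "NA")]
        )
        frame = make_frame([[1.234, -5.678, 9.012], [0.5, 0.25, -0.125]])
        path = tmp_path / "rt.pdb"
        write_topology(path, top, frame)
        top2, frame2 = read_topology(path)
        assert [a.residue_id for a in top2.atoms] == [7, 2]
        assert top2.atoms[0].chain_id == "B"
        assert top2.atoms[1].species == "NA"
        assert np.allclose(frame2.coords, frame.coords, atol=1e-3)

    def test_vdw_metadata_round_trip(self, tmp_path):
        atom = protein_atom(1, "PSD", 1, "PSD", element="C")
        atom.vdw_A = 1.65
        top = Topology([atom, protein_atom(2, "CA", 2, element="C")])
        frame = make_frame([[0, 0, 0], [3, 0, 0]])
        path = tmp_path / "vdw.pdb"
        write_topology(path, top, frame)
        top2, _ = read_topology(path, bfactor_as_vdw=True)
        assert top2.atoms[0].vdw_A == pytest.approx(1.65, abs=1e-6)
        assert top2.atoms[1].vdw_A is None


class TestNativeDialect:
    def test_round_trip_preserves_coordinates(self, tmp_path, four_atom_topology):
        rng = np.random.default_rng(7)
        traj = make_traj(four_atom_topology, rng.uniform(0, 50, size=(3, 4, 3)))
        path = tmp_path / "t.jsonl"
        write_native(path, traj)
        traj2 = read_frames(path, four_atom_topology)
        assert traj2.n_frames == 3
        assert np.allclose(traj2.coords_array(), traj.coords_array(), atol=1e-6)
        assert np.allclose(traj2.times_ns, traj.times_ns)

    def test_atom_count_mismatch(self, tmp_path, four_atom_topology):
        traj = make_traj(four_atom_topology, np.zeros((1, 4, 3)) + np.arange(4)[:, None])
        path = tmp_path / "t.jsonl"
        write_native(path, traj)
        small_top = Topology([protein_atom(1, "CA", 1, element="C")])
        with pytest.raises(ShapeError):
            read_frames(path, small_top)

    def test_unknown_extension(self, tmp_path, four_atom_topology):
        p = tmp_path / "t.xyz"
        p.write_text("")
        with pytest.raises(FormatError):
            read_frames(p, four_atom_topology)


class TestBinaryFormats:
    @pytest.mark.parametrize("ext", ["dcd", "xtc"])
    def test_mdanalysis_round_trip(self, tmp_path, four_atom_topology, ext):
        import MDAnalysis as mda

        rng = np.random.default_rng(11)
        X = rng.uniform(5, 45, size=(3, 4, 3))
        u = mda.Universe.empty(4, trajectory=True)
        path = tmp_path / f"t.{ext}"
        with mda.Writer(str(path), n_atoms=4) as w:
            for i in range(3):
                u.atoms.positions = X[i]
                u.trajectory.ts.dimensions = [50, 50, 50, 90, 90, 90]
                u.trajectory.ts.dt = 1.0
                w.write(u.atoms)
        traj = read_frames(path, four_atom_topology)
        assert traj.n_frames == 3
        assert np.allclose(traj.coords_array(), X, atol=1e-2)

    def test_dcd_atom_count_mismatch(self, tmp_path, four_atom_topology):
        import MDAnalysis as mda

        u = mda.Universe.empty(5, trajectory=True)
        path = tmp_path / "t.dcd"
        with mda.Writer(str(path), n_atoms=5) as w:
            u.atoms.positions = np.zeros((5, 3))
            w.write(u.atoms)
        with pytest.raises(ShapeError):
            read_frames(path, four_atom_topology)


class TestUnwrap:
    def test_minimum_image_step(self):
        top = Topology([ion_atom(1, "NA")])
        traj = make_traj(top, [[[99.0, 50, 50]], [[1.0, 50, 50]]])
        un = unwrap_coordinates(traj, axes=("x",))
        assert un.frames[1].coords[0, 0] == pytest.approx(101.0)

    def test_stationary_atom_unchanged(self, four_atom_topology, four_atom_coords):
        traj = make_traj(four_atom_topology, [four_atom_coords] * 4)
        un = unwrap_coordinates(traj)
        assert np.allclose(un.coords_array(), traj.coords_array())

    def test_drift_accumulates_across_images(self):
        # +0.4 Å/frame for 500 frames in an L=100 box: net +200 Å.
        top = Topology([ion_atom(1, "NA")])
        true_x = 10.0 + 0.4 * np.arange(501)
        wrapped = np.mod(true_x, 100.0)
        coords = np.zeros((501, 1, 3))
        coords[:, 0, 0] = wrapped
        traj = make_traj(top, coords)
        un = unwrap_coordinates(traj, axes=("x",))
        # cumulative-sum oracle over wrapped increments
        d = np.diff(wrapped)
        d -= 100.0 * np.round(d / 100.0)
        oracle = 10.0 + np.concatenate([[0.0], np.cumsum(d)])
        assert np.allclose(un.coords_array()[:, 0, 0], oracle, atol=1e-9)
        assert un.frames[-1].coords[0, 0] - un.frames[0].coords[0, 0] == pytest.approx(
            200.0
        )

    def test_idempotent(self):
        top = Topology([ion_atom(1, "NA")])
        rng = np.random.default_rng(3)
        steps = rng.uniform(-20, 20, size=50)
        x = 50 + np.concatenate([[0.0], np.cumsum(steps)])
        coords = np.zeros((51, 1, 3))
        coords[:, 0, 0] = np.mod(x, 100.0)
        traj = make_traj(top, coords)
        once = unwrap_coordinates(traj, axes=("x",))
        twice = unwrap_coordinates(once, axes=("x",))
        assert np.allclose(once.coords_array(), twice.coords_array(), atol=1e-9)


class TestRmsd:
    def test_identical_frame_is_zero(self, four_atom_topology, four_atom_coords):
        traj = make_traj(four_atom_topology, [four_atom_coords] * 3)
        out = rmsd_timeseries(traj, backbone_selection(), superpose=False)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_rigid_transform_invariance_with_superposition(
        self, four_atom_topology, four_atom_coords
    ):
        moved = rigid_transform(four_atom_coords)
        traj = make_traj(four_atom_topology, [four_atom_coords, moved])
        out = rmsd_timeseries(traj, backbone_selection(), superpose=True)
        assert out[1] <= 1e-8

    def test_single_displacement_closed_form(
        self, four_atom_topology, four_atom_coords
    ):
        # one of four atoms displaced by d: RMSD = d/sqrt(N) = 0.5
        moved = four_atom_coords.copy()
        moved[0, 2] += 1.0
        traj = make_traj(four_atom_topology, [four_atom_coords, moved])
        out = rmsd_timeseries(traj, backbone_selection(), superpose=False)
        assert out[1] == pytest.approx(0.5, abs=1e-10)

    def test_superposed_never_exceeds_raw(self, four_atom_topology):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 10, size=(6, 4, 3))
        traj = make_traj(four_atom_topology, coords)
        sup = rmsd_timeseries(traj, backbone_selection(), superpose=True)
        raw = rmsd_timeseries(traj, backbone_selection(), superpose=False)
        assert np.all(sup <= raw + 1e-9)

    def test_empty_selection_raises(self, four_atom_topology, four_atom_coords):
        traj = make_traj(four_atom_topology, [four_atom_coords])
        with pytest.raises(SelectionError):
            rmsd_timeseries(traj, select(names={"ZZ"}))


class TestRmsf:
    def test_static_trajectory_is_zero(self, four_atom_topology, four_atom_coords):
        traj = make_traj(four_atom_topology, [four_atom_coords] * 4)
        out = rmsf_per_residue(traj, backbone_selection(), superpose=False)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in out.values())

    def test_alternating_displacement_closed_form(self, four_atom_topology):
        # one atom alternates ±a about its mean along x: RMSF = a
        a = 0.7
        base = np.zeros((4, 3))
        base[1, 0] = 5.0
        base[2, 1] = 5.0
        base[3, 2] = 5.0
        frames = []
        for i in range(6):
            c = base.copy()
            c[0, 0] = a if i % 2 == 0 else -a
            frames.append(c)
        traj = make_traj(four_atom_topology, frames)
        out = rmsf_per_residue(
            traj, select(names={"N"}), superpose=False
        )
        assert out[("A", 1, "GLY")] == pytest.approx(a, abs=1e-12)

    def test_global_translation_invariance(self, four_atom_topology, four_atom_coords):
        frames = [four_atom_coords + i * np.array([1.0, -2.0, 0.5]) for i in range(5)]
        traj = make_traj(four_atom_topology, frames)
        out = rmsf_per_residue(traj, backbone_selection(), superpose=True)
        assert all(v <= 1e-8 for v in out.values())

    def test_single_frame_raises(self, four_atom_topology, four_atom_coords):
        traj = make_traj(four_atom_topology, [four_atom_coords])
        with pytest.raises(InsufficientDataError):
            rmsf_per_residue(traj, backbone_selection())


class TestSelections:
    def test_species_and_ion_selection(self):
        top = Topology(
            [protein_atom(1, "CA", 1, element="C"), ion_atom(2, "NA"), ion_atom(3, "CL")]
        )
        assert list(ion_selection().resolve(top)) == [1, 2]
        assert list(ion_selection(["CL"]).resolve(top)) == [2]

    def test_invariants(self, four_atom_topology):
        idx = backbone_selection().resolve(four_atom_topology)
        assert set(idx) <= set(range(four_atom_topology.n_atoms))
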