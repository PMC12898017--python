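"""Shared fixtures: small topologies and trajectories built in memory."""

from __future__ import annotations

import numpy as np
import pytest

from paraperm.traj import Atom, Frame, Topology, Trajectory


def make_frame(coords, box=(100.0, 100.0, 100.0), index=0, time_ns=None):
    return Frame(
        index=index,
        time_ns=float(index) if time_ns is None else time_ns,
        box_lengths=np.asarray(box, dtype=float),
        coords=np.asarray(coords, dtype=float),
    )


def make_traj(topology, coord_list, box=(100.0, 100.0, 100.0)):
    frames = [make_frame(c, box=box, index=i) for i, c in enumerate(coord_list)]
    return Trajectory(topology, frames)


def protein_atom(atom_id, name, resid, resname="GLY", chain="A", element=None):
    if element is None:
        element = name[0]
    return Atom(atom_id, name, element, resname, resid, chain)


def ion_atom(atom_id, species, resid=None):
    return Atom(
        atom_id,
        species,
        species[0],
        species,
        resid if resid is not None else atom_id,
        "I",
        species=species,
    )


@pytest.fixture
def four_atom_topology():
    """A single glycine backbone: N, CA, C, O."""
    return Topology(
        [
            protein_atom(1, "N", 1),
            protein_atom(2, "CA", 1, element="C"),
            protein_atom(3, "C", 1),
            protein_atom(4, "O", 1),
        ]
    )


@pytest.fixture
def four_atom_coords():
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [1.5, 0.0, 0.0],
            [2.3, 1.2, 0.0],
            [3.5, 1.4, 0.5],
        ]
    )


def rigid_transform(coords, angle_deg=90.0, axis=(0, 0, 1.0), shift=(5.0, -3.0, 2.0)):
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * np.asarray(axis, dtype=float))
    return rot.apply(coords) + np.asarray(shift)
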