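import numpy as np
import pytest

from cosolvkb import (AtomRecord, Frame, Trajectory, gen_shell_protein)


@pytest.fixture
def two_atom_traj():
    """Minimal two-atom fixture: one TBA bead and one water in a 4 nm cube."""
    topo = [
        AtomRecord(index=0, name="TB", species="tba", residue_index=1,
                   residue_name="TBA", mass=74.12, vdw_radius=0.15),
        AtomRecord(index=1, name="OW", species="water", residue_index=2,
                   residue_name="SOL", mass=18.015, vdw_radius=0.152),
    ]
    frame = Frame(positions=np.array([[0.5, 1.0, 1.5], [2.0, 2.5, 3.0]]),
                  box=np.array([4.0, 4.0, 4.0]))
    return Trajectory(topology=topo, frames=[frame])


@pytest.fixture(scope="session")
def shell_fixture():
    """Toy protein with a 0.25 nm solute shell plus bulk solute and solvent."""
    return gen_shell_protein(
        n_residues=20, shell_spec=[(0.25, 12)], bulk=(20, 400),
        box=(6.0, 6.0, 6.0), frames=30, seed=421)


def make_single_atoms(positions, box, species="water", resname="SOL",
                      name="OW", mass=18.015, frames=None):
    """Build a trajectory of single-atom molecules at explicit positions."""
    positions = np.asarray(positions, dtype=float)
    topo = [AtomRecord(index=i, name=name, species=species,
                       residue_index=i + 1, residue_name=resname, mass=mass,
                       vdw_radius=0.15)
            for i in range(len(positions))]
    if frames is None:
        frames = [Frame(positions=positions, box=np.asarray(box, float))]
    else:
        frames = [Frame(positions=p, box=np.asarray(box, float))
                  for p in frames]
    return Trajectory(topology=topo, frames=frames)
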