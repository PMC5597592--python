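import numpy as np
import pytest

from crossres import synthgen, trajio


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pseudo_lipid():
    """11-particle two-chain base structure + particle table."""
    return synthgen.make_pseudo_lipid(n_head=3, n_tail=4, tails=2)


@pytest.fixture
def small_system(pseudo_lipid):
    """3 copies x 200 frames, 2 planted modes, no rigid motion."""
    base, table = pseudo_lipid
    modes = synthgen.random_orthonormal_modes(base, 2, seed=7)
    spec = synthgen.SyntheticSpec(
        base, table, modes,
        planted_eigenvalues=np.array([4.0, 1.0]),
        mode_relaxation_times=np.array([10.0, 5.0]),
        noise_floor=0.02, n_copies=3, n_frames=200, seed=7,
    )
    traj, truth = synthgen.generate_system(spec)
    return traj, truth, spec


@pytest.fixture
def pdb_file(tmp_path):
    """Hand-written 5-atom PDB (one residue, one hydrogen)."""
    lines = [
        "ATOM      1  C1  LIP A   1       1.000   0.000   0.000  1.00  0.00           C",
        "ATOM      2  C2  LIP A   1       2.500   0.000   0.000  1.00  0.00           C",
        "ATOM      3  O1  LIP A   1       2.500   1.500   0.000  1.00  0.00           O",
        "ATOM      4  H12 LIP A   1       0.500   0.800   0.000  1.00  0.00           H",
        "ATOM      5  N1  LIP A   1       3.500   2.000   1.000  1.00  0.00           N",
        "END",
    ]
    path = tmp_path / "five.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def gro_file(tmp_path):
    path = tmp_path / "two.gro"
    path.write_text(
        "two atoms\n"
        "    2\n"
        "    1LIP     C1    1   1.000   2.000   3.000\n"
        "    1LIP     H1    2   0.100   0.200   0.300\n"
        "   5.00000   5.00000   5.00000\n"
    )
    return path


def write_text_traj(path, coords):
    traj_coords = np.asarray(coords, float)
    with open(path, "w") as fh:
        fh.write(f"{traj_coords.shape[0]} {traj_coords.shape[1]}\n")
        for frame in traj_coords:
            np.savetxt(fh, frame, fmt="%.8f")
    return path


@pytest.fixture
def mapping_file(tmp_path):
    path = tmp_path / "scheme.map"
    path.write_text(
        "; two disjoint 2-atom beads over 4 atoms\n"
        "[atoms]\n"
        "a b c d\n"
        "B1: a b\n"
        "B2: c d*1\n"
    )
    return path


@pytest.fixture
def tiled_trajectory(pseudo_lipid):
    """3 identical copies of the pseudo-lipid over 4 frames, shifted apart."""
    base, table = pseudo_lipid
    n_copies, n_frames = 3, 4
    coords = np.empty((n_frames, n_copies * len(table), 3))
    for c in range(n_copies):
        coords[:, c * len(table) : (c + 1) * len(table), :] = base + np.array([30.0 * c, 0, 0])
    full = trajio.ParticleTable.from_names(
        list(table.names) * n_copies,
        list(table.residue_names) * n_copies,
        np.repeat(np.arange(n_copies), len(table)),
        elements=list(table.elements) * n_copies,
    )
    return trajio.Trajectory(coords, full)
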