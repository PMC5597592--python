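"""Structure/trajectory/mapping file I/O and per-molecule ensemble extraction.

Internal length unit is the angstrom everywhere; GRO nanometre values are
converted on read (MDAnalysis already follows this convention).  Indices
are 0-based in the data model and 1-based only inside file formats.

Supported formats
-----------------
Structures: PDB (ATOM/HETATM) and GRO, via MDAnalysis.
Trajectories: XTC, DCD, multi-model PDB (via MDAnalysis) and a plain-text
frame format: a header line ``T N`` followed by ``T`` blocks of ``N``
lines ``x y z`` in angstroms.

Mapping dialect (text)::

    ; comment
    [atoms]
    C1 C2 C3 C4
    BEAD1: C1 C2*0.5
    BEAD2: C3 C4

Unweighted atoms get weight 1; every row is rescaled to sum to 1 on load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cgmap import MappingScheme
from .errors import (
    EmptySelectionError,
    MappingDefinitionError,
    ParseError,
    ShapeError,
    TopologyError,
    ValidationError,
)

__all__ = [
    "ParticleTable",
    "Trajectory",
    "MoleculeEnsemble",
    "infer_element",
    "read_structure",
    "read_trajectory",
    "write_trajectory",
    "write_structure",
    "extract_molecule_ensemble",
    "read_mapping",
    "unwrap_molecules",
]

_STRUCT_FORMATS = {".pdb": "pdb", ".gro": "gro"}
_TRAJ_FORMATS = {".xtc": "xtc", ".dcd": "dcd", ".pdb": "multi_pdb", ".txt": "text", ".dat": "text"}


def infer_element(name: str) -> str:
    """Element from an atom name: leading digits stripped, first alphabetic
    character decides; ``H`` means hydrogen.  Returns ``""`` when no letter
    is found (caller warns and treats the particle as heavy)."""
    stripped = name.lstrip("0123456789 ")
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return ""


@dataclass(frozen=True)
class ParticleTable:
    """Per-particle metadata with contiguous 0-based ids."""

    names: tuple[str, ...]
    residue_names: tuple[str, ...]
    residue_ids: np.ndarray
    elements: tuple[str, ...]
    is_heavy: np.ndarray

    def __post_init__(self):
        rid = np.asarray(self.residue_ids, dtype=int)
        heavy = np.asarray(self.is_heavy, dtype=bool)
        object.__setattr__(self, "residue_ids", rid)
        object.__setattr__(self, "is_heavy", heavy)
        n = len(self.names)
        if not all(self.names):
            raise ValidationError("every particle must have a non-empty name")
        if len(self.residue_names) != n or rid.size != n or len(self.elements) != n or heavy.size != n:
            raise ShapeError("particle table columns have inconsistent lengths")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def particle_ids(self) -> np.ndarray:
        return np.arange(len(self))

    @classmethod
    def from_names(cls, names, residue_names, residue_ids, elements=None) -> "ParticleTable":
        names = tuple(str(n) for n in names)
        if elements is None:
            elements = []
            for n in names:
                el = infer_element(n)
                if el == "":
                    warnings.warn(f"cannot infer element for atom '{n}'; treating as heavy")
                elements.append(el)
        elements = tuple(elements)
        heavy = np.array([el != "H" for el in elements], dtype=bool)
        return cls(names, tuple(str(r) for r in residue_names), np.asarray(residue_ids, int), elements, heavy)

    def subset(self, indices) -> "ParticleTable":
        idx = np.asarray(indices, dtype=int)
        return ParticleTable(
            tuple(self.names[i] for i in idx),
            tuple(self.residue_names[i] for i in idx),
            self.residue_ids[idx],
            tuple(self.elements[i] for i in idx),
            self.is_heavy[idx],
        )


@dataclass
class Trajectory:
    """T x N x 3 coordinate array (angstrom) with particle metadata."""

    coordinates: np.ndarray
    particles: ParticleTable
    frame_interval: float | None = None
    box: np.ndarray | None = None

    def __post_init__(self):
        c = np.asarray(self.coordinates, dtype=float)
        if c.ndim != 3 or c.shape[2] != 3:
            raise ShapeError(f"coordinates must be (T, N, 3), got {c.shape}")
        if c.shape[0] < 1:
            raise ValidationError("trajectory must contain at least one frame")
        if not np.all(np.isfinite(c)):
            raise ValidationError("coordinates contain non-finite values")
        if c.shape[1] != len(self.particles):
            raise ShapeError(
                f"frame has {c.shape[1]} particles but table lists {len(self.particles)}"
            )
        self.coordinates = c
        if self.box is not None:
            b = np.atleast_2d(np.asarray(self.box, dtype=float))
            if b.shape[0] == 1:
                b = np.repeat(b, c.shape[0], axis=0)
            if b.shape != (c.shape[0], 3):
                raise ShapeError("box must be a per-frame 3-vector of lengths")
            if np.any(b <= 0):
                raise ValidationError("box lengths must be strictly positive")
            self.box = b

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class MoleculeEnsemble:
    """Conformations pooled over molecule copies and frames (copy-major)."""

    conformations: np.ndarray
    source_labels: np.ndarray  # (K, 2): copy index, frame index
    n_copies: int
    particle_names: tuple[str, ...] = ()
    frame_interval: float | None = None

    def __post_init__(self):
        c = np.asarray(self.conformations, dtype=float)
        if c.ndim != 3 or c.shape[2] != 3:
            raise ShapeError("conformations must be (K, N_p, 3)")
        self.conformations = c
        self.source_labels = np.asarray(self.source_labels, dtype=int)
        if self.source_labels.shape != (c.shape[0], 2):
            raise ShapeError("source_labels must be (K, 2)")

    @property
    def n_conformations(self) -> int:
        return self.conformations.shape[0]

    @property
    def n_particles(self) -> int:
        return self.conformations.shape[1]

    @property
    def n_frames(self) -> int:
        return self.n_conformations // self.n_copies

    def per_copy(self) -> np.ndarray:
        """Reshape to (N_L, T, N_p, 3); valid because pooling is copy-major."""
        return self.conformations.reshape(self.n_copies, self.n_frames, self.n_particles, 3)


def _mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def read_structure(path, format: str | None = None) -> tuple[ParticleTable, np.ndarray]:
    """Read a PDB or GRO file into a particle table and N x 3 angstrom coordinates."""
    path = Path(path)
    fmt = format or _STRUCT_FORMATS.get(path.suffix.lower())
    if fmt not in ("pdb", "gro"):
        raise ParseError(f"unsupported structure format for '{path}'")
    mda = _mda()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=fmt)
        coords = u.atoms.positions.astype(float).copy()
        names = [a.name for a in u.atoms]
        resnames = [a.resname for a in u.atoms]
        resids = [a.resid for a in u.atoms]
    except (OSError, FileNotFoundError):
        raise
    except Exception as exc:  # MDAnalysis raises assorted parser errors
        raise ParseError(f"failed to parse {fmt.upper()} file '{path}': {exc}") from exc
    table = ParticleTable.from_names(names, resnames, resids)
    return table, coords


def _read_text_frames(path) -> np.ndarray:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ParseError(f"'{path}': expected header 'T N', got {header!r} (line 1)")
        try:
            t, n = int(header[0]), int(header[1])
        except ValueError as exc:
            raise ParseError(f"'{path}': non-integer header (line 1)") from exc
        data = np.loadtxt(fh, dtype=float, ndmin=2)
    if data.size != t * n * 3:
        frames_read = data.shape[0] // max(n, 1)
        raise ParseError(
            f"'{path}': truncated trajectory — header promises {t} frames of {n} "
            f"particles, last complete frame is {frames_read - 1}"
        )
    return data.reshape(t, n, 3)


def read_trajectory(path, particles: ParticleTable, format: str | None = None) -> Trajectory:
    """Read a multi-frame trajectory against a known particle table."""
    path = Path(path)
    fmt = format or _TRAJ_FORMATS.get(path.suffix.lower())
    if fmt is None:
        raise ParseError(f"cannot infer trajectory format for '{path}'")
    n = len(particles)
    if fmt == "text":
        coords = _read_text_frames(path)
        if coords.shape[1] != n:
            raise ShapeError(
                f"trajectory frames have {coords.shape[1]} particles, table has {n}"
            )
        return Trajectory(coords, particles)
    mda = _mda()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if fmt == "multi_pdb":
                u = mda.Universe(str(path), format="pdb")
            else:
                u = mda.Universe.empty(n, trajectory=True)
                u.load_new(str(path), format=fmt)
    except (OSError, FileNotFoundError):
        raise
    except Exception as exc:
        raise ParseError(f"failed to read trajectory '{path}': {exc}") from exc
    if u.atoms.n_atoms != n:
        raise ShapeError(f"trajectory frames have {u.atoms.n_atoms} particles, table has {n}")
    frames, boxes = [], []
    dt = None
    for ts in u.trajectory:
        frames.append(ts.positions.astype(float).copy())
        if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            boxes.append(ts.dimensions[:3].astype(float).copy())
        if dt is None and getattr(ts, "dt", 0):
            dt = float(ts.dt)
    box = np.array(boxes) if len(boxes) == len(frames) and boxes else None
    return Trajectory(np.array(frames), particles, frame_interval=dt, box=box)


def write_trajectory(traj: Trajectory, path, format: str | None = None) -> None:
    """Write a trajectory as text, XTC or DCD."""
    path = Path(path)
    fmt = format or _TRAJ_FORMATS.get(path.suffix.lower())
    if fmt == "text":
        with open(path, "w") as fh:
            fh.write(f"{traj.n_frames} {traj.n_particles}\n")
            for frame in traj.coordinates:
                np.savetxt(fh, frame, fmt="%.6f")
        return
    if fmt not in ("xtc", "dcd"):
        raise ParseError(f"unsupported trajectory output format for '{path}'")
    mda = _mda()
    u = mda.Universe.empty(traj.n_particles, trajectory=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.n_particles) as w:
            for i, frame in enumerate(traj.coordinates):
                u.atoms.positions = frame
                if traj.box is not None:
                    u.dimensions = [*traj.box[i], 90.0, 90.0, 90.0]
                w.write(u.atoms)


def write_structure(particles: ParticleTable, coords: np.ndarray, path, box=None) -> None:
    """Write a single-model PDB or GRO structure."""
    path = Path(path)
    fmt = _STRUCT_FORMATS.get(path.suffix.lower())
    if fmt is None:
        raise ParseError(f"unsupported structure output format for '{path}'")
    mda = _mda()
    n = len(particles)
    u = mda.Universe.empty(n, n_residues=len(set(particles.residue_ids.tolist())), atom_resindex=_resindex(particles), trajectory=True)
    u.add_TopologyAttr("names", list(particles.names))
    resorder = _unique_in_order(particles.residue_ids)
    u.add_TopologyAttr("resnames", [_resname_for(particles, r) for r in resorder])
    u.add_TopologyAttr("resids", [int(r) + 1 for r in resorder])
    u.atoms.positions = np.asarray(coords, dtype=float)
    if box is not None:
        u.dimensions = [*np.asarray(box, float), 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def _unique_in_order(values) -> list:
    seen, out = set(), []
    for v in np.asarray(values).tolist():
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


def _resindex(particles: ParticleTable) -> np.ndarray:
    order = {r: i for i, r in enumerate(_unique_in_order(particles.residue_ids))}
    return np.array([order[r] for r in particles.residue_ids.tolist()])


def _resname_for(particles: ParticleTable, resid) -> str:
    idx = int(np.nonzero(particles.residue_ids == resid)[0][0])
    return particles.residue_names[idx]


def extract_molecule_ensemble(
    traj: Trajectory, residue_name: str, heavy_only: bool = True
) -> MoleculeEnsemble:
    """Pool per-molecule sub-trajectories of all residues named `residue_name`.

    Conformations are ordered copy-major, frame-minor (copy 0 frames
    0..T-1, then copy 1, ...), which fixes the PCA input ordering and
    makes downstream results bit-reproducible.
    """
    table = traj.particles
    match = np.array([rn == residue_name for rn in table.residue_names], dtype=bool)
    if not match.any():
        raise EmptySelectionError(f"no particles with residue name '{residue_name}'")
    matched_rids = _unique_in_order(table.residue_ids[match])
    copies = []
    for rid in matched_rids:
        idx = np.nonzero((table.residue_ids == rid) & match)[0]
        copies.append(idx)
    ref_names = tuple(table.names[i] for i in copies[0])
    for c, idx in enumerate(copies[1:], start=1):
        names = tuple(table.names[i] for i in idx)
        if names != ref_names:
            for k, (a, b) in enumerate(zip(ref_names, names)):
                if a != b:
                    raise TopologyError(
                        f"copy {c} differs from copy 0 at particle {k}: '{b}' vs '{a}'"
                    )
            raise TopologyError(f"copy {c} has {len(names)} particles, copy 0 has {len(ref_names)}")
    if heavy_only:
        keep = np.nonzero(table.is_heavy[copies[0]])[0]
        copies = [idx[keep] for idx in copies]
        ref_names = tuple(ref_names[k] for k in keep)
    n_l, t = len(copies), traj.n_frames
    n_p = len(copies[0])
    conf = np.empty((n_l * t, n_p, 3))
    labels = np.empty((n_l * t, 2), dtype=int)
    for c, idx in enumerate(copies):
        conf[c * t : (c + 1) * t] = traj.coordinates[:, idx, :]
        labels[c * t : (c + 1) * t, 0] = c
        labels[c * t : (c + 1) * t, 1] = np.arange(t)
    return MoleculeEnsemble(conf, labels, n_l, ref_names, traj.frame_interval)


def unwrap_molecules(traj: Trajectory) -> Trajectory:
    """Minimum-image shift of each particle relative to the first particle
    of its molecule, using the frame box.  Heuristic for molecules split
    across periodic boundaries; assumes each molecule spans < half a box."""
    if traj.box is None:
        raise ValidationError("unwrap requires box information")
    coords = traj.coordinates.copy()
    rids = traj.particles.residue_ids
    for rid in _unique_in_order(rids):
        idx = np.nonzero(rids == rid)[0]
        anchor = coords[:, idx[0] : idx[0] + 1, :]
        delta = coords[:, idx, :] - anchor
        box = traj.box[:, None, :]
        coords[:, idx, :] = anchor + delta - box * np.round(delta / box)
    return Trajectory(coords, traj.particles, traj.frame_interval, traj.box)


def read_mapping(path) -> MappingScheme:
    """Parse the text mapping dialect into a normalized MappingScheme."""
    atom_names: list[str] = []
    beads: list[tuple[str, list[tuple[str, float]]]] = []
    in_atoms = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split(";", 1)[0].strip()
            if not line:
                continue
            if line.lower() == "[atoms]":
                in_atoms = True
                continue
            if ":" in line:
                in_atoms = False
                bead_name, rest = line.split(":", 1)
                bead_name = bead_name.strip()
                if not bead_name:
                    raise ParseError(f"mapping line {lineno}: empty bead name")
                entries = []
                for token in rest.split():
                    if "*" in token:
                        aname, _, wstr = token.partition("*")
                        try:
                            weight = float(wstr)
                        except ValueError as exc:
                            raise ParseError(
                                f"mapping line {lineno}: bad weight '{wstr}'"
                            ) from exc
                    else:
                        aname, weight = token, 1.0
                    entries.append((aname, weight))
                if not entries:
                    raise MappingDefinitionError(
                        f"mapping line {lineno}: bead '{bead_name}' references no atoms"
                    )
                beads.append((bead_name, entries))
            elif in_atoms:
                atom_names.extend(line.split())
            else:
                raise ParseError(f"mapping line {lineno}: unexpected content '{line}'")
    if not atom_names:
        raise ParseError(f"'{path}': missing [atoms] block")
    if not beads:
        raise MappingDefinitionError(f"'{path}': no beads defined")
    index = {a: j for j, a in enumerate(atom_names)}
    w = np.zeros((len(beads), len(atom_names)))
    for i, (bead_name, entries) in enumerate(beads):
        for aname, weight in entries:
            if aname not in index:
                raise MappingDefinitionError(
                    f"bead '{bead_name}' references undeclared atom '{aname}'"
                )
            w[i, index[aname]] += weight
    rowsums = w.sum(axis=1)
    if np.any(np.abs(rowsums - 1.0) > 1e-12):
        warnings.warn("mapping rows rescaled to sum to 1")
    return MappingScheme.normalized(w, [b for b, _ in beads], atom_names)
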