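"""Trajectory core: topology/trajectory containers, I/O, unwrapping, RMSD/RMSF.

Coordinates are Å, times ns, everywhere. File readers convert at the
boundary (MDAnalysis reports ps for DCD/XTC; divided by 1000 on read).

The native trajectory dialect is JSON-lines: one frame per line with
fields ``{"index", "time_ns", "box", "coords"}`` — chosen so synthetic
fixtures are plain text and human-diffable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    FormatError,
    InsufficientDataError,
    ParseError,
    SelectionError,
    ShapeError,
)
from .species import RESNAME_TO_SPECIES

WATER_RESNAMES = frozenset({"HOH", "TIP3", "WAT", "SOL", "SPC", "TIP4"})

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


def axis_index(axis: str | int) -> int:
    """Map an axis label ('x'/'y'/'z' or 0/1/2) to a coordinate index."""
    if isinstance(axis, int):
        if axis not in (0, 1, 2):
            raise ValueError(f"axis index must be 0, 1 or 2, got {axis}")
        return axis
    try:
        return _AXIS_INDEX[axis.lower()]
    except KeyError:
        raise ValueError(f"unknown axis {axis!r}") from None


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Atom:
    """One atom (or ion / pseudo-atom) record.

    ``species`` is set for ions (e.g. "NA", "CL", "TMA") and None for
    protein/water atoms. ``vdw_A`` optionally overrides the element-based
    van der Waals radius (used by pseudo-atom pore fixtures).
    """

    atom_id: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    species: str | None = None
    vdw_A: float | None = None

    def __post_init__(self) -> None:
        if self.atom_id < 0:
            raise ValueError("atom_id must be >= 0")
        if not self.element:
            raise ValueError("element must be non-empty")


class Topology:
    """Ordered atom list plus a (chain_id, residue_id) → atom-ids index."""

    def __init__(self, atoms: Sequence[Atom]):
        self.atoms: list[Atom] = list(atoms)
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise ValueError("atom_id values must be unique within a topology")
        self.residue_index: dict[tuple[str, int], list[int]] = {}
        for a in self.atoms:
            self.residue_index.setdefault((a.chain_id, a.residue_id), []).append(
                a.atom_id
            )
        self._id_to_pos = {a.atom_id: i for i, a in enumerate(self.atoms)}

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def positions_of(self, atom_ids: Iterable[int]) -> np.ndarray:
        """Array positions (row indices) for the given atom ids."""
        return np.asarray([self._id_to_pos[i] for i in atom_ids], dtype=np.intp)

    def residue_of(self, atom_id: int) -> tuple[str, int, str]:
        a = self.atoms[self._id_to_pos[atom_id]]
        return (a.chain_id, a.residue_id, a.residue_name)

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class Frame:
    """One trajectory frame: coordinates (Å) plus orthorhombic box lengths."""

    index: int
    time_ns: float
    box_lengths: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.box_lengths = np.asarray(self.box_lengths, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.time_ns < 0:
            raise ValueError("time_ns must be >= 0")
        if self.box_lengths.shape != (3,) or not np.all(self.box_lengths > 0):
            raise ValueError("box_lengths must be 3 strictly positive lengths")
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ShapeError(f"coords must be (n_atoms, 3), got {self.coords.shape}")


class Trajectory:
    """A topology plus ordered frames with strictly increasing time."""

    def __init__(self, topology: Topology, frames: Sequence[Frame]):
        frames = list(frames)
        if not frames:
            raise ValueError("a trajectory needs at least one frame")
        n = topology.n_atoms
        for f in frames:
            if f.coords.shape[0] != n:
                raise ShapeError(
                    f"frame {f.index}: {f.coords.shape[0]} atoms, topology has {n}"
                )
        times = np.array([f.time_ns for f in frames])
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        self.topology = topology
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times_ns(self) -> np.ndarray:
        return np.array([f.time_ns for f in self.frames])

    def coords_array(self) -> np.ndarray:
        """Stack of coordinates, shape (n_frames, n_atoms, 3)."""
        return np.stack([f.coords for f in self.frames])

    def with_coords(self, coords: np.ndarray) -> "Trajectory":
        """New trajectory with replaced coordinates (same topology/frames)."""
        frames = [
            replace(f, coords=coords[i]) for i, f in enumerate(self.frames)
        ]
        return Trajectory(self.topology, frames)


@dataclass
class Selection:
    """Declarative atom selection over topology attributes.

    All provided criteria must match (conjunction); ``predicate`` is an
    arbitrary extra test on the Atom.
    """

    names: frozenset[str] | None = None
    elements: frozenset[str] | None = None
    resnames: frozenset[str] | None = None
    resids: frozenset[int] | None = None
    chains: frozenset[str] | None = None
    species: frozenset[str] | None = None
    predicate: Callable[[Atom], bool] | None = None
    label: str = ""

    def matches(self, atom: Atom) -> bool:
        if self.names is not None and atom.name not in self.names:
            return False
        if self.elements is not None and atom.element not in self.elements:
            return False
        if self.resnames is not None and atom.residue_name not in self.resnames:
            return False
        if self.resids is not None and atom.residue_id not in self.resids:
            return False
        if self.chains is not None and atom.chain_id not in self.chains:
            return False
        if self.species is not None and atom.species not in self.species:
            return False
        if self.predicate is not None and not self.predicate(atom):
            return False
        return True

    def resolve(self, topology: Topology) -> np.ndarray:
        """Row indices (into coordinate arrays) of matching atoms, in order."""
        idx = np.array(
            [i for i, a in enumerate(topology.atoms) if self.matches(a)],
            dtype=np.intp,
        )
        return idx

    def resolve_or_raise(self, topology: Topology) -> np.ndarray:
        idx = self.resolve(topology)
        if idx.size == 0:
            raise SelectionError(f"selection {self.label or self!r} matched no atoms")
        return idx


def select(
    names: Iterable[str] | None = None,
    elements: Iterable[str] | None = None,
    resnames: Iterable[str] | None = None,
    resids: Iterable[int] | None = None,
    chains: Iterable[str] | None = None,
    species: Iterable[str] | None = None,
    predicate: Callable[[Atom], bool] | None = None,
    label: str = "",
) -> Selection:
    """Convenience constructor accepting any iterables."""

    def fs(x):
        return None if x is None else frozenset(x)

    return Selection(
        fs(names), fs(elements), fs(resnames), fs(resids), fs(chains),
        fs(species), predicate, label,
    )


def backbone_selection(calpha_only: bool = False) -> Selection:
    """Protein backbone: atom names N, CA, C, O (or Cα only)."""
    names = {"CA"} if calpha_only else {"N", "CA", "C", "O"}
    return select(
        names=names,
        predicate=lambda a: a.species is None
        and a.residue_name not in WATER_RESNAMES,
        label="backbone",
    )


def ion_selection(species: Iterable[str] | None = None) -> Selection:
    """All ion atoms, optionally restricted to given species labels."""
    if species is None:
        return select(predicate=lambda a: a.species is not None, label="ions")
    return select(species=species, label="ions")


# ---------------------------------------------------------------------------
# PDB topology I/O
# ---------------------------------------------------------------------------


def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise ParseError(f"line {lineno}: malformed {what} field {text.strip()!r}")


def read_topology(
    path: str | Path, bfactor_as_vdw: bool = False
) -> tuple[Topology, Frame]:
    """Read a PDB file into a Topology plus the single coordinate Frame.

    Fixed-column ATOM/HETATM parsing; malformed records raise
    :class:`ParseError` naming the line number. When ``bfactor_as_vdw``
    is set, a positive B-factor is stored as the per-atom vdW radius
    (the convention used by pseudo-atom pore fixtures).

    The frame's box is taken from a CRYST1 record if present, else a
    bounding box with 10 Å padding.
    """
    path = Path(path)
    atoms: list[Atom] = []
    coords: list[tuple[float, float, float]] = []
    box: np.ndarray | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "CRYST1":
                box = np.array(
                    [
                        _parse_float(line[6:15], "box a", lineno),
                        _parse_float(line[15:24], "box b", lineno),
                        _parse_float(line[24:33], "box c", lineno),
                    ]
                )
                continue
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError(
                    f"line {lineno}: truncated coordinate record "
                    f"({len(line.rstrip())} chars, need >= 54)"
                )
            try:
                serial = int(line[6:11])
            except ValueError:
                raise ParseError(f"line {lineno}: malformed atom serial {line[6:11]!r}")
            name = line[12:16].strip()
            resname = line[17:21].strip()
            chain = line[21].strip() or "A"
            try:
                resid = int(line[22:26])
            except ValueError:
                raise ParseError(f"line {lineno}: malformed residue id {line[22:26]!r}")
            x = _parse_float(line[30:38], "x coordinate", lineno)
            y = _parse_float(line[38:46], "y coordinate", lineno)
            z = _parse_float(line[46:54], "z coordinate", lineno)
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = "".join(c for c in name if c.isalpha())[:1].upper() or "X"
            vdw = None
            if bfactor_as_vdw and len(line) >= 66:
                b = line[60:66].strip()
                if b:
                    bval = _parse_float(line[60:66], "B-factor", lineno)
                    vdw = bval if bval > 0 else None
            species = RESNAME_TO_SPECIES.get(resname) if rec == "HETATM" else None
            atoms.append(
                Atom(
                    atom_id=serial,
                    name=name,
                    element=element,
                    residue_name=resname,
                    residue_id=resid,
                    chain_id=chain,
                    species=species,
                    vdw_A=vdw,
                )
            )
            coords.append((x, y, z))
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    xyz = np.asarray(coords)
    if box is None:
        span = xyz.max(axis=0) - xyz.min(axis=0)
        box = span + 20.0
    top = Topology(atoms)
    frame = Frame(index=0, time_ns=0.0, box_lengths=box, coords=xyz)
    return top, frame


def write_topology(path: str | Path, topology: Topology, frame: Frame) -> None:
    """Write a PDB file; per-atom vdW radii (if set) go to the B-factor column."""
    with open(path, "w") as fh:
        b = frame.box_lengths
        fh.write(
            f"CRYST1{b[0]:9.3f}{b[1]:9.3f}{b[2]:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
        )
        for a, (x, y, z) in zip(topology.atoms, frame.coords):
            rec = "HETATM" if a.species is not None else "ATOM  "
            vdw = a.vdw_A if a.vdw_A is not None else 0.0
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            fh.write(
                f"{rec}{a.atom_id % 100000:5d} {name[:4]:<4s} "
                f"{a.residue_name[:4]:<4s}{a.chain_id[:1]}{a.residue_id % 10000:4d}"
                f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{vdw:6.2f}"
                f"          {a.element[:2]:>2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Frame I/O: native JSONL, DCD, XTC
# ---------------------------------------------------------------------------


def write_native(path: str | Path, traj: Trajectory) -> None:
    """Write frames in the native JSON-lines dialect (one frame per line)."""
    with open(path, "w") as fh:
        for f in traj.frames:
            fh.write(
                json.dumps(
                    {
                        "index": f.index,
                        "time_ns": f.time_ns,
                        "box": f.box_lengths.tolist(),
                        "coords": f.coords.tolist(),
                    }
                )
            )
            fh.write("\n")


def _read_native_frames(path: Path, n_atoms: int) -> list[Frame]:
    frames: list[Frame] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as e:
                raise ParseError(f"line {lineno}: invalid JSON ({e.msg})")
            try:
                frame = Frame(
                    index=int(obj["index"]),
                    time_ns=float(obj["time_ns"]),
                    box_lengths=np.asarray(obj["box"], dtype=float),
                    coords=np.asarray(obj["coords"], dtype=float),
                )
            except KeyError as e:
                raise ParseError(f"line {lineno}: missing field {e.args[0]!r}")
            if frame.coords.shape[0] != n_atoms:
                raise ShapeError(
                    f"line {lineno}: frame has {frame.coords.shape[0]} atoms, "
                    f"topology has {n_atoms}"
                )
            frames.append(frame)
    if not frames:
        raise ParseError(f"{path}: no frames")
    return frames


def _read_mda_frames(path: Path, n_atoms: int) -> list[Frame]:
    if path.suffix.lower() == ".dcd":
        from MDAnalysis.coordinates.DCD import DCDReader as Reader
    else:
        from MDAnalysis.coordinates.XTC import XTCReader as Reader
    reader = Reader(str(path))
    if reader.n_atoms != n_atoms:
        reader.close()
        raise ShapeError(
            f"{path.name}: {reader.n_atoms} atoms per frame, topology has {n_atoms}"
        )
    frames: list[Frame] = []
    times_ps: list[float] = []
    for i, ts in enumerate(reader):
        dims = ts.dimensions
        if dims is None or not np.all(np.asarray(dims[:3]) > 0):
            box = np.array([1e6, 1e6, 1e6])
        else:
            box = np.asarray(dims[:3], dtype=float)
        times_ps.append(float(ts.time))
        frames.append(
            Frame(
                index=i,
                time_ns=0.0 if i == 0 else float(i),  # provisional
                box_lengths=box,
                coords=np.asarray(ts.positions, dtype=float),
            )
        )
    reader.close()
    t = np.asarray(times_ps) / 1000.0  # MDAnalysis reports ps
    if not np.all(np.diff(t) > 0):
        t = np.arange(len(frames), dtype=float)  # fall back to frame index
    for f, ti in zip(frames, t):
        f.time_ns = float(ti)
    return frames


def read_frames(path: str | Path, topology: Topology) -> Trajectory:
    """Read coordinate frames (native .jsonl, .dcd or .xtc) against a topology."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext in (".jsonl", ".njson", ".ndjson"):
        frames = _read_native_frames(path, topology.n_atoms)
    elif ext in (".dcd", ".xtc"):
        frames = _read_mda_frames(path, topology.n_atoms)
    else:
        raise FormatError(f"unknown trajectory extension {ext!r} for {path.name}")
    return Trajectory(topology, frames)


# ---------------------------------------------------------------------------
# Periodic-boundary unwrapping
# ---------------------------------------------------------------------------


def unwrap_coordinates(
    traj: Trajectory, axes: Sequence[str | int] = ("x", "y", "z")
) -> Trajectory:
    """Accumulate minimum-image inter-frame increments along the given axes.

    Per axis, each frame-to-frame increment is reduced into (−L/2, L/2]
    with the current frame's box length, then cumulatively summed from
    the first frame's coordinates; non-selected axes are untouched. Valid
    when true inter-frame displacements are below half a box length
    (undetectable if violated). Idempotent on already-unwrapped input.
    """
    ax = sorted({axis_index(a) for a in axes})
    X = traj.coords_array()
    out = X.copy()
    for j in ax:
        d = np.diff(X[:, :, j], axis=0)
        L = np.array([f.box_lengths[j] for f in traj.frames[1:]])[:, None]
        d -= L * np.round(d / L)
        out[1:, :, j] = X[0, :, j] + np.cumsum(d, axis=0)
    return traj.with_coords(out)


# ---------------------------------------------------------------------------
# Structural stability metrics
# ---------------------------------------------------------------------------


def _superpose(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Optimal rigid-body superposition (Kabsch) of mobile onto ref."""
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - rc, mobile - mc)
    return rot.apply(mobile - mc) + rc


def rmsd_timeseries(
    traj: Trajectory,
    sel: Selection,
    reference: int = 0,
    superpose: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (Å) of the selected atoms relative to a reference frame.

    With ``superpose``, each frame is first optimally rigid-body
    superposed (least-squares, Kabsch) onto the reference selection.
    """
    idx = sel.resolve_or_raise(traj.topology)
    X = traj.coords_array()[:, idx, :]
    ref = X[reference]
    out = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        mob = _superpose(X[i], ref) if superpose else X[i]
        out[i] = np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1)))
    return out


def rmsf_per_residue(
    traj: Trajectory,
    sel: Selection,
    superpose: bool = True,
    reference: int = 0,
) -> dict[tuple[str, int, str], float]:
    """Per-residue RMSF (Å): atomic fluctuation about the time-mean position,
    averaged over each residue's selected atoms.

    With ``superpose``, frames are first superposed onto the reference
    frame's selection so that global rigid drift does not inflate the
    fluctuations.
    """
    if traj.n_frames < 2:
        raise InsufficientDataError("RMSF needs at least 2 frames")
    idx = sel.resolve_or_raise(traj.topology)
    X = traj.coords_array()[:, idx, :]
    if superpose:
        ref = X[reference]
        X = np.stack([_superpose(X[i], ref) for i in range(X.shape[0])])
    mean_pos = X.mean(axis=0)
    atomic_rmsf = np.sqrt(np.mean(np.sum((X - mean_pos) ** 2, axis=2), axis=0))
    result: dict[tuple[str, int, str], list[float]] = {}
    for k, aid_pos in enumerate(idx):
        atom = traj.topology.atoms[aid_pos]
        key = (atom.chain_id, atom.residue_id, atom.residue_name)
        result.setdefault(key, []).append(atomic_rmsf[k])
    return {k: float(np.mean(v)) for k, v in result.items()}


def minimum_image_deltas(
    points_a: np.ndarray, points_b: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """Pairwise minimum-image displacement vectors a[i] − b[j], shape (A, B, 3)."""
    d = points_a[:, None, :] - points_b[None, :, :]
    d -= box * np.round(d / box)
    return d


def minimum_image_distances(
    points_a: np.ndarray, points_b: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """Pairwise minimum-image distances, shape (A, B)."""
    return np.linalg.norm(minimum_image_deltas(points_a, points_b, box), axis=2)
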