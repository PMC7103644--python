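"""Trajectory data model, structure/trajectory I/O, selections, and the
periodic-distance primitive shared by every analysis module.

Internal units are fixed: lengths in nm, times in ps, masses in amu, angles
in degrees. Conversions (PDB ångström, cutoff strings like ``"5 A"``) happen
only at the I/O and config boundaries. Boxes are orthorhombic; triclinic
input raises :class:`UnsupportedBoxError`.

File reading and writing is delegated to MDAnalysis; the in-memory
containers defined here are deliberately small, array-backed and immutable
in spirit, so analysis code never touches a reader object.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

import MDAnalysis as mda
from MDAnalysis.coordinates.XTC import XTCWriter

__all__ = [
    "Atom",
    "Topology",
    "Frame",
    "Trajectory",
    "Selection",
    "TrajModelError",
    "FormatError",
    "UnsupportedBoxError",
    "SelectionError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "select",
    "minimum_image_displacement",
    "minimum_image_distance",
    "parse_length",
]

A_TO_NM = 0.1
NM_TO_A = 10.0


class TrajModelError(ValueError):
    """Base error for the data-model layer."""


class FormatError(TrajModelError):
    """A structure or trajectory file could not be parsed."""


class UnsupportedBoxError(TrajModelError):
    """Non-orthorhombic (triclinic) periodic box."""


class SelectionError(TrajModelError):
    """A selection expression is invalid or matches nothing."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """A single particle (atom or coarse-grained bead)."""

    index: int
    name: str
    residue_name: str
    residue_id: int
    segment_id: str
    mass: float
    is_bead: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise TrajModelError("atom name must be non-empty")
        if self.mass < 0:
            raise TrajModelError(f"atom {self.index}: negative mass {self.mass}")


class Topology:
    """Ordered atom table with vectorised per-field access.

    Atom indices are 0-based; residue ids are 1-based as in the source
    files. Field arrays (``names``, ``resids`` ...) are numpy arrays used
    by :func:`select` and by the analysis modules.
    """

    def __init__(self, atoms: Sequence[Atom]):
        atoms = list(atoms)
        indices = [a.index for a in atoms]
        if len(set(indices)) != len(indices):
            raise TrajModelError("atom indices must be unique within a Topology")
        self.atoms: list[Atom] = atoms
        self.names = np.array([a.name for a in atoms], dtype=object)
        self.resnames = np.array([a.residue_name for a in atoms], dtype=object)
        self.resids = np.array([a.residue_id for a in atoms], dtype=np.int64)
        self.segids = np.array([a.segment_id for a in atoms], dtype=object)
        self.masses = np.array([a.mass for a in atoms], dtype=float)
        self.is_bead = np.array([a.is_bead for a in atoms], dtype=bool)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def residue_groups(self, indices: np.ndarray | None = None):
        """Yield ``(segid, resid, resname, atom_indices)`` in file order.

        Restricted to ``indices`` when given. Grouping key is
        ``(segment_id, residue_id)`` so duplicated residue numbers across
        chains stay distinct.
        """
        if indices is None:
            indices = np.arange(self.n_atoms)
        seen: dict[tuple, list[int]] = {}
        order: list[tuple] = []
        for i in np.asarray(indices, dtype=int):
            key = (self.segids[i], int(self.resids[i]))
            if key not in seen:
                seen[key] = []
                order.append(key)
            seen[key].append(int(i))
        for key in order:
            idx = np.array(seen[key], dtype=int)
            yield key[0], key[1], self.resnames[idx[0]], idx


@dataclass
class Frame:
    """One coordinate set: N×3 positions (nm), orthorhombic box (nm), time (ps)."""

    coordinates: np.ndarray
    box: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise TrajModelError("coordinates must be N×3")
        if not np.all(np.isfinite(self.coordinates)):
            raise TrajModelError("non-finite coordinate encountered")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,):
                raise UnsupportedBoxError(
                    "box must be 3 orthorhombic edge lengths; triclinic boxes "
                    "are not supported"
                )

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Trajectory:
    """An ordered frame sequence bound to one Topology."""

    topology: Topology
    frames: list[Frame]
    frame_stride_ps: float = 0.0

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise TrajModelError("a Trajectory needs at least one frame")
        times = [f.time for f in self.frames]
        if any(t1 < t0 for t0, t1 in zip(times, times[1:])):
            raise TrajModelError("frame times must be non-decreasing")
        for f in self.frames:
            if f.n_atoms != self.topology.n_atoms:
                raise TrajModelError(
                    f"frame has {f.n_atoms} atoms but topology has "
                    f"{self.topology.n_atoms}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)

    def __iter__(self):
        return iter(self.frames)


@dataclass(frozen=True)
class Selection:
    """A labelled, order-stable set of atom indices into one Topology."""

    label: str
    atom_indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.atom_indices, dtype=np.int64)
        object.__setattr__(self, "atom_indices", idx)
        if idx.size == 0:
            raise SelectionError(f"selection {self.label!r} is empty")

    def __len__(self) -> int:
        return int(self.atom_indices.size)


# ---------------------------------------------------------------------------
# I/O (MDAnalysis-backed)
# ---------------------------------------------------------------------------

def _box_from_mda(dimensions) -> np.ndarray | None:
    if dimensions is None:
        return None
    dims = np.asarray(dimensions, dtype=float)
    if dims.size < 6 or np.all(dims[:3] == 0):
        return None
    alpha, beta, gamma = dims[3:6]
    if not (np.isclose(alpha, 90) and np.isclose(beta, 90) and np.isclose(gamma, 90)):
        raise UnsupportedBoxError(
            f"triclinic box (angles {alpha:.1f}/{beta:.1f}/{gamma:.1f}) is not supported"
        )
    return dims[:3] * A_TO_NM


def _topology_from_universe(u: "mda.Universe") -> Topology:
    n = len(u.atoms)
    try:
        masses = np.asarray(u.atoms.masses, dtype=float)
        if not np.all(np.isfinite(masses)) or np.all(masses == 0):
            raise ValueError
    except Exception:
        warnings.warn(
            "masses unavailable in file; falling back to equal unit masses",
            stacklevel=3,
        )
        masses = np.ones(n)
    # zero/unguessable individual masses (e.g. CG beads) fall back to 1 amu
    bad = ~np.isfinite(masses) | (masses <= 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} atoms have no usable mass; using 1 amu for those",
            stacklevel=3,
        )
        masses = np.where(bad, 1.0, masses)
    try:
        segids = u.atoms.segids
    except Exception:
        segids = np.array(["SYSTEM"] * n, dtype=object)
    try:
        chainids = u.atoms.chainIDs
        use = np.array(
            [c if str(c).strip() else s for c, s in zip(chainids, segids)],
            dtype=object,
        )
        segids = use
    except Exception:
        pass
    atoms = [
        Atom(
            index=i,
            name=str(u.atoms.names[i]),
            residue_name=str(u.atoms.resnames[i]),
            residue_id=int(u.atoms.resids[i]),
            segment_id=str(segids[i]),
            mass=float(masses[i]),
        )
        for i in range(n)
    ]
    return Topology(atoms)


def read_structure(path: str) -> tuple[Topology, Frame]:
    """Read a PDB or GRO file into (Topology, Frame), coordinates in nm.

    PDB coordinates (Å) are converted to nm. A GRO file without its final
    box line is rejected. Non-finite coordinates raise :class:`FormatError`.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in {".pdb", ".gro"}:
        raise FormatError(f"unsupported structure format {ext!r} (need .pdb or .gro)")
    if ext == ".gro":
        _check_gro_box_line(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(path)
        except UnsupportedBoxError:
            raise
        except Exception as exc:  # locate the offending line for the report
            lineno = _locate_bad_line(path, ext)
            raise FormatError(f"cannot parse {path!r} (near line {lineno}): {exc}") from exc
    topology = _topology_from_universe(u)
    coords = np.asarray(u.atoms.positions, dtype=float) * A_TO_NM
    if not np.all(np.isfinite(coords)):
        bad = int(np.argwhere(~np.isfinite(coords))[0][0])
        raise FormatError(f"non-finite coordinate for atom index {bad} in {path!r}")
    box = _box_from_mda(u.dimensions)
    if ext == ".gro" and box is None:
        raise FormatError(f"GRO file {path!r} has no box line")
    return topology, Frame(coordinates=coords, box=box, time=0.0)


def _check_gro_box_line(path: str) -> None:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) < 3:
        raise FormatError(f"GRO file {path!r} too short (line {len(lines)})")
    try:
        vals = [float(x) for x in lines[-1].split()]
    except ValueError:
        raise FormatError(
            f"GRO file {path!r}: last line (line {len(lines)}) is not a box line"
        )
    if len(vals) < 3:
        raise FormatError(f"GRO file {path!r} has no box line (line {len(lines)})")


def _locate_bad_line(path: str, ext: str) -> int:
    """Best-effort line number of the first malformed record."""
    try:
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                if ext == ".pdb" and line[:6].strip() in {"ATOM", "HETATM"}:
                    try:
                        float(line[30:38]); float(line[38:46]); float(line[46:54])
                    except ValueError:
                        return i
                if ext == ".gro" and i >= 3 and line.strip():
                    fields = line[20:].split()
                    if fields:
                        try:
                            [float(x) for x in fields[:3]]
                        except ValueError:
                            return i
    except OSError:
        pass
    return 0


_TRAJ_EXTS = {".xtc", ".trr", ".dcd", ".pdb"}


def read_trajectory(path: str, topology: Topology) -> Trajectory:
    """Read XTC/TRR/DCD (or multi-model PDB) frames against ``topology``.

    Units are normalised to nm/ps. Raises on atom-count mismatch, stating
    both counts.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise FormatError(f"trajectory file {path!r} is empty")
    ext = os.path.splitext(path)[1].lower()
    if ext not in _TRAJ_EXTS:
        raise FormatError(f"unsupported trajectory format {ext!r}")
    reader_cls = {
        ".xtc": mda.coordinates.XTC.XTCReader,
        ".trr": mda.coordinates.TRR.TRRReader,
        ".dcd": mda.coordinates.DCD.DCDReader,
        ".pdb": mda.coordinates.PDB.PDBReader,
    }[ext]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            reader = reader_cls(path)
        except Exception as exc:
            raise FormatError(f"cannot open trajectory {path!r}: {exc}") from exc
        if reader.n_atoms != topology.n_atoms:
            reader.close()
            raise TrajModelError(
                f"trajectory {path!r} has {reader.n_atoms} atoms but the "
                f"topology has {topology.n_atoms}"
            )
        frames = []
        for ts in reader:
            frames.append(
                Frame(
                    coordinates=np.asarray(ts.positions, dtype=float) * A_TO_NM,
                    box=_box_from_mda(ts.dimensions),
                    time=float(ts.time),
                )
            )
        reader.close()
    stride = frames[1].time - frames[0].time if len(frames) > 1 else 0.0
    return Trajectory(topology=topology, frames=frames, frame_stride_ps=stride)


def _universe_from(topology: Topology, frame: Frame) -> "mda.Universe":
    n = topology.n_atoms
    # residue table in file order, keyed by (segid, resid)
    res_keys: list[tuple] = []
    atom_resindex = np.empty(n, dtype=int)
    for i in range(n):
        key = (topology.segids[i], int(topology.resids[i]))
        if not res_keys or res_keys[-1] != key:
            res_keys.append(key)
        atom_resindex[i] = len(res_keys) - 1
    seg_keys = sorted({k[0] for k in res_keys})
    seg_index = {s: j for j, s in enumerate(seg_keys)}
    res_segindex = np.array([seg_index[k[0]] for k in res_keys], dtype=int)
    u = mda.Universe.empty(
        n,
        n_residues=len(res_keys),
        n_segments=len(seg_keys),
        atom_resindex=atom_resindex,
        residue_segindex=res_segindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(x) for x in topology.names])
    u.add_TopologyAttr("masses", topology.masses)
    u.add_TopologyAttr("resids", [k[1] for k in res_keys])
    u.add_TopologyAttr(
        "resnames",
        [str(topology.resnames[np.where(atom_resindex == r)[0][0]]) for r in range(len(res_keys))],
    )
    u.add_TopologyAttr("segids", [str(s) for s in seg_keys])
    u.atoms.positions = frame.coordinates * NM_TO_A
    if frame.box is not None:
        u.dimensions = np.array([*(frame.box * NM_TO_A), 90.0, 90.0, 90.0])
    return u


def write_structure(path: str, topology: Topology, frame: Frame) -> None:
    """Write a single frame to PDB or GRO (extension decides the format)."""
    ext = os.path.splitext(path)[1].lower()
    if ext not in {".pdb", ".gro"}:
        raise FormatError(f"unsupported structure format {ext!r}")
    u = _universe_from(topology, frame)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(path)


def write_trajectory(path: str, trajectory: Trajectory) -> None:
    """Write all frames to an XTC file (or multi-model PDB)."""
    ext = os.path.splitext(path)[1].lower()
    u = _universe_from(trajectory.topology, trajectory.frames[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if ext == ".xtc":
            with XTCWriter(path, n_atoms=trajectory.topology.n_atoms) as w:
                for i, f in enumerate(trajectory.frames):
                    u.atoms.positions = f.coordinates * NM_TO_A
                    if f.box is not None:
                        u.dimensions = np.array([*(f.box * NM_TO_A), 90.0, 90.0, 90.0])
                    u.trajectory.ts.time = f.time
                    u.trajectory.ts.frame = i
                    w.write(u.atoms)
        elif ext == ".pdb":
            with mda.Writer(path, multiframe=True, n_atoms=trajectory.topology.n_atoms) as w:
                for f in trajectory.frames:
                    u.atoms.positions = f.coordinates * NM_TO_A
                    w.write(u.atoms)
        else:
            raise FormatError(f"unsupported trajectory output format {ext!r}")


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def _parse_int_set(tokens: list[str]) -> np.ndarray:
    out: list[int] = []
    for tok in tokens:
        if "-" in tok and not tok.lstrip("-").isdigit():
            lo, hi = tok.split("-", 1)
            out.extend(range(int(lo), int(hi) + 1))
        else:
            out.append(int(tok))
    return np.array(out, dtype=np.int64)


_KEYWORDS = {"segment", "segid", "resid", "resname", "name", "index", "all"}


def _eval_primitive(topology: Topology, tokens: list[str]) -> np.ndarray:
    if not tokens:
        raise SelectionError("empty selection term")
    kw, args = tokens[0], tokens[1:]
    if kw == "all":
        return np.ones(topology.n_atoms, dtype=bool)
    if kw not in _KEYWORDS:
        raise SelectionError(f"unknown selection keyword {kw!r}")
    if not args:
        raise SelectionError(f"selection keyword {kw!r} needs arguments")
    if kw in {"segment", "segid"}:
        return np.isin(topology.segids, args)
    if kw == "resname":
        return np.isin(topology.resnames, args)
    if kw == "name":
        return np.isin(topology.names, args)
    if kw == "resid":
        return np.isin(topology.resids, _parse_int_set(args))
    if kw == "index":
        return np.isin(np.arange(topology.n_atoms), _parse_int_set(args))
    raise SelectionError(f"unhandled keyword {kw!r}")  # pragma: no cover


def select(topology: Topology, expression: str, label: str | None = None) -> Selection:
    """Evaluate a selection expression, e.g. ``"segment A and resid 153-189"``.

    Grammar: primitives ``segment``, ``resid`` (ranges like ``153-189``),
    ``resname``, ``name``, ``index``, ``all``; combined with ``and`` / ``or``
    (``and`` binds tighter); a leading ``not`` negates one primitive.
    The result is a deterministic, ascending index list; an empty result is
    an error because every downstream analysis is undefined on it.
    """
    expr = expression.strip()
    if not expr:
        raise SelectionError("empty selection expression")
    or_mask = np.zeros(topology.n_atoms, dtype=bool)
    for or_part in expr.split(" or "):
        and_mask = np.ones(topology.n_atoms, dtype=bool)
        for term in or_part.split(" and "):
            tokens = term.split()
            negate = False
            if tokens and tokens[0] == "not":
                negate = True
                tokens = tokens[1:]
            m = _eval_primitive(topology, tokens)
            and_mask &= ~m if negate else m
        or_mask |= and_mask
    indices = np.flatnonzero(or_mask)
    if indices.size == 0:
        raise SelectionError(f"selection {expression!r} matches no atoms")
    return Selection(label=label or expression, atom_indices=indices)


# ---------------------------------------------------------------------------
# Periodic-distance primitive
# ---------------------------------------------------------------------------

def minimum_image_displacement(r1: np.ndarray, r2: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Minimum-image displacement r1−r2 in an orthorhombic box (nm).

    Broadcasts over leading dimensions. With ``box=None`` the plain
    difference is returned. Every component of the result has magnitude
    ≤ half the corresponding box edge.
    """
    d = np.asarray(r1, dtype=float) - np.asarray(r2, dtype=float)
    if box is None:
        return d
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise TrajModelError(f"box edges must be positive, got {box}")
    return d - box * np.round(d / box)


def minimum_image_distance(r1: np.ndarray, r2: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Euclidean norm of :func:`minimum_image_displacement` over the last axis."""
    return np.linalg.norm(minimum_image_displacement(r1, r2, box), axis=-1)


# ---------------------------------------------------------------------------
# Config-boundary unit parsing
# ---------------------------------------------------------------------------

_UNIT_FACTORS = {"nm": 1.0, "a": 0.1, "å": 0.1, "angstrom": 0.1, "ang": 0.1}


def parse_length(value) -> float:
    """Parse a length with an explicit unit tag into nm.

    Accepts ``"5 A"``, ``"0.65 nm"``, ``"6.5A"``, or a bare number (taken
    as nm). Explicit tags are preferred in configs to avoid Å/nm mixups.
    """
    if isinstance(value, (int, float)):
        return float(value)
    s = str(value).strip().lower()
    for unit, factor in _UNIT_FACTORS.items():
        if s.endswith(unit):
            num = s[: -len(unit)].strip()
            if num:
                return float(num) * factor
    return float(s)
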