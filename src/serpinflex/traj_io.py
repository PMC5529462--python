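"""Structure and trajectory I/O plus atom selection.

Coordinates are in Angstrom and frame intervals in picoseconds throughout.
Residue numbers are taken verbatim from the input file (they may be
negative, as in serpin constructs whose N-terminal extension is numbered
below 1); insertion codes are rejected.

Two trajectory dialects are supported behind one contract:

* a plain-text frame table (read/write, bit-exact round trip) — one header
  line ``<n_atoms> <frame_interval_ps>`` followed, per frame, by one line
  per atom ``serial x y z`` with 6 decimal places;
* binary DCD/XTC through mdtraj's low-level format readers (read only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "AtomSelector",
    "PdbParseError",
    "EmptyStructureError",
    "EmptySelectionError",
    "TopologyError",
    "TrajectoryIOError",
    "read_pdb",
    "read_trajectory",
    "write_trajectory",
    "stream_frames",
    "select",
]


class PdbParseError(ValueError):
    """Malformed PDB record; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class EmptyStructureError(ValueError):
    pass


class EmptySelectionError(ValueError):
    pass


class TopologyError(ValueError):
    pass


class TrajectoryIOError(IOError):
    pass


@dataclass
class Atom:
    """A single atom with its PDB-style identity and position in Angstrom."""

    serial: int
    name: str
    element: str
    res_name: str
    res_num: int
    chain: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.key()}")

    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.res_num, self.name)


@dataclass
class Structure:
    """An ordered set of atoms; atom order defines frame column order."""

    atoms: list[Atom]
    title: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyStructureError("structure contains no atoms")
        keys = [a.key() for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen: set[tuple[str, int, str]] = set()
            dup = next(k for k in keys if k in seen or seen.add(k))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate atom identity {dup}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate matrix in file order."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def res_nums(self) -> list[int]:
        """Residue numbers in order of first appearance."""
        out: list[int] = []
        for a in self.atoms:
            if not out or a.res_num != out[-1]:
                if a.res_num not in out:
                    out.append(a.res_num)
        return out


@dataclass
class Trajectory:
    """A topology plus time-ordered coordinate frames.

    ``frames`` is an (n_frames, n_atoms, 3) array in Angstrom; frame *k*
    is at time ``k * frame_interval`` ps.
    """

    topology: Structure
    frames: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"frames have {self.frames.shape[1]} atoms, "
                f"topology has {self.topology.n_atoms}"
            )
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive (ps)")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class AtomSelector:
    """Declarative atom selection by chain, residue number(s) and atom name.

    ``res_nums`` accepts a single int, an iterable of ints, or a range;
    ``atom_names`` defaults to Cα only.
    """

    chain: str | None = None
    res_nums: int | Iterable[int] | None = None
    atom_names: frozenset[str] | set[str] | None = field(
        default_factory=lambda: {"CA"}
    )

    def _res_set(self) -> set[int] | None:
        if self.res_nums is None:
            return None
        if isinstance(self.res_nums, int):
            return {self.res_nums}
        return set(self.res_nums)

    def matches(self, atom: Atom) -> bool:
        if self.chain is not None and atom.chain != self.chain:
            return False
        res = self._res_set()
        if res is not None and atom.res_num not in res:
            return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        return True


def select(structure: Structure, selector: AtomSelector) -> list[int]:
    """Resolve a selector to an ordered list of atom indices.

    Indices are ordered by residue number, then by atom order within the
    residue, so selection is stable under atom reordering inside a residue
    block. Raises :class:`EmptySelectionError` if nothing matches.
    """
    hits = [i for i, a in enumerate(structure.atoms) if selector.matches(a)]
    if not hits:
        raise EmptySelectionError(f"selector {selector} matched no atoms")
    hits.sort(key=lambda i: (structure.atoms[i].res_num, i))
    return hits


# --- PDB reading -----------------------------------------------------------

_RECORDS = ("ATOM  ", "HETATM")


def read_pdb(path: str | Path) -> Structure:
    """Read ATOM/HETATM records from a PDB file.

    Alternate locations are collapsed to a single conformer per
    (chain, res_num, name): the highest occupancy wins, ties go to altloc
    "A". Insertion codes are unsupported and raise a parse error. Residue
    numbers are parsed as signed integers exactly as written.
    """
    path = Path(path)
    chosen: dict[tuple[str, int, str], tuple[Atom, float, str]] = {}
    order: list[tuple[str, int, str]] = []
    title = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("TITLE"):
                title = (title + " " + line[10:].strip()).strip()
            if not line.startswith(_RECORDS):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PdbParseError("truncated coordinate record", lineno)
            icode = line[26]
            if icode not in (" ", ""):
                raise PdbParseError(
                    f"insertion code {icode!r} is unsupported", lineno
                )
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                altloc = line[16]
                res_name = line[17:20].strip()
                chain = line[21].strip()
                res_num = int(line[22:26])
                pos = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            except ValueError as exc:
                raise PdbParseError(str(exc), lineno) from exc
            occ_field = line[54:60].strip()
            occupancy = float(occ_field) if occ_field else 1.0
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = name[:1]
            atom = Atom(serial, name, element, res_name, res_num, chain,
                        np.array(pos))
            key = atom.key()
            if key not in chosen:
                chosen[key] = (atom, occupancy, altloc)
                order.append(key)
            else:
                _, old_occ, old_alt = chosen[key]
                if occupancy > old_occ or (
                    occupancy == old_occ and altloc == "A" and old_alt != "A"
                ):
                    chosen[key] = (atom, occupancy, altloc)
    if not chosen:
        raise EmptyStructureError(f"no ATOM/HETATM records in {path}")
    return Structure([chosen[k][0] for k in order], title=title)


# --- plain-text frame-table dialect ---------------------------------------


def write_trajectory(traj: Trajectory, path: str | Path,
                     dialect: str = "text") -> None:
    """Write a trajectory; only the plain-text dialect is writable."""
    if dialect != "text":
        raise ValueError(f"unwritable dialect {dialect!r}")
    serials = [a.serial for a in traj.topology.atoms]
    with open(path, "w") as fh:
        fh.write(f"{traj.topology.n_atoms} {traj.frame_interval:.6f}\n")
        for frame in traj.frames:
            for serial, (x, y, z) in zip(serials, frame):
                fh.write(f"{serial} {x:.6f} {y:.6f} {z:.6f}\n")


def stream_frames(path: str | Path,
                  n_atoms: int | None = None) -> Iterator[np.ndarray]:
    """Yield (n_atoms, 3) frames from a plain-text trajectory one at a time.

    Constant memory in the number of frames; used both by the reader and
    for frame counting on large files.
    """
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise TrajectoryIOError(f"malformed header in {path}")
        file_atoms = int(header[0])
        if n_atoms is not None and file_atoms != n_atoms:
            raise TopologyError(
                f"file has {file_atoms} atoms per frame, expected {n_atoms}"
            )
        frame_idx = 0
        while True:
            rows = []
            for i in range(file_atoms):
                line = fh.readline()
                if not line:
                    if i == 0:
                        return
                    raise TrajectoryIOError(
                        f"truncated frame {frame_idx} in {path}"
                    )
                parts = line.split()
                if len(parts) != 4:
                    raise TrajectoryIOError(
                        f"bad atom line in frame {frame_idx} of {path}"
                    )
                rows.append([float(parts[1]), float(parts[2]), float(parts[3])])
            yield np.array(rows)
            frame_idx += 1


def _read_text_header(path: str | Path) -> tuple[int, float]:
    with open(path) as fh:
        header = fh.readline().split()
    if len(header) != 2:
        raise TrajectoryIOError(f"malformed header in {path}")
    return int(header[0]), float(header[1])


def read_trajectory(path: str | Path, topology: Structure,
                    dialect: str | None = None,
                    frame_interval: float | None = None) -> Trajectory:
    """Read a trajectory against a topology.

    ``dialect`` is "text", "dcd" or "xtc"; if None it is inferred from the
    file extension (default "text"). Binary formats do not carry a reliable
    frame interval, so ``frame_interval`` (ps) must be given for them.
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower()
        dialect = {".dcd": "dcd", ".xtc": "xtc"}.get(suffix, "text")
    if dialect == "text":
        n_atoms, interval = _read_text_header(path)
        if n_atoms != topology.n_atoms:
            raise TopologyError(
                f"file has {n_atoms} atoms per frame, topology has "
                f"{topology.n_atoms}"
            )
        frames = list(stream_frames(path, n_atoms=topology.n_atoms))
        if not frames:
            raise TrajectoryIOError(f"no frames in {path}")
        return Trajectory(topology, np.stack(frames), interval)
    if dialect in ("dcd", "xtc"):
        if frame_interval is None:
            raise ValueError(f"frame_interval (ps) required for {dialect}")
        xyz = _read_binary(path, dialect)
        if xyz.shape[1] != topology.n_atoms:
            raise TopologyError(
                f"file has {xyz.shape[1]} atoms per frame, topology has "
                f"{topology.n_atoms}"
            )
        return Trajectory(topology, xyz, frame_interval)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_binary(path: Path, dialect: str) -> np.ndarray:
    # mdtraj low-level readers keep each format's native length unit:
    # DCD is Angstrom, XTC is nm.
    if dialect == "dcd":
        from mdtraj.formats import DCDTrajectoryFile

        with DCDTrajectoryFile(str(path)) as fh:
            xyz, _, _ = fh.read()
        return np.asarray(xyz, dtype=float)
    from mdtraj.formats import XTCTrajectoryFile

    with XTCTrajectoryFile(str(path)) as fh:
        xyz, _, _, _ = fh.read()
    return np.asarray(xyz, dtype=float) * 10.0
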