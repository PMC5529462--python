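"""Inter-atom distance series, backbone hydrogen-bond lengths, helix
integrity and strand-detachment event detection.

Hydrogen bonds are measured as heavy-atom backbone N···O distances; no
hydrogens or angle criterion are involved, which matches Cα-level analysis
of backbone donors/acceptors. A helix (or strand pairing) whose *average*
bond length exceeds 3.5 Angstrom must have at least one broken bond, since
intact hydrogen bonds are shorter than that.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .traj_io import AtomSelector, EmptySelectionError, Trajectory, select

__all__ = [
    "HBondDefinition",
    "DistanceSeries",
    "DetachmentEvent",
    "SelectionError",
    "atom_distance_series",
    "hbond_length_series",
    "helix_integrity_series",
    "detachment_events",
    "helix_bond_set",
    "read_bond_config",
    "write_series_table",
    "BOND_SETS",
    "DISTANCE_PAIRS",
    "HBOND_BREAK_THRESHOLD",
]

#: Average backbone H-bond length (Angstrom) above which at least one bond
#: in the set must be broken.
HBOND_BREAK_THRESHOLD = 3.5


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class HBondDefinition:
    """A backbone N-H···O=C hydrogen bond named by its heavy atoms."""

    donor: tuple[int, str]      # (res_num, "N")
    acceptor: tuple[int, str]   # (res_num, "O")
    label: str = ""

    def __post_init__(self):
        if not self.label:
            object.__setattr__(
                self, "label",
                f"{self.acceptor[0]}{self.acceptor[1]}:"
                f"{self.donor[0]}{self.donor[1]}",
            )


@dataclass
class DistanceSeries:
    label: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(self.values <= 0):
            raise ValueError("distances must be positive")


@dataclass
class DetachmentEvent:
    """A maximal interval during which a monitored distance stayed above
    its breakage threshold."""

    label: str
    start_time: float
    end_time: float
    max_length: float


def _resolve_single(traj: Trajectory, selector: AtomSelector) -> int:
    try:
        idx = select(traj.topology, selector)
    except EmptySelectionError as exc:
        raise SelectionError(str(exc)) from exc
    if len(idx) != 1:
        raise SelectionError(
            f"selector {selector} resolved to {len(idx)} atoms, expected 1"
        )
    return idx[0]


def atom_distance_series(traj: Trajectory, sel_a: AtomSelector,
                         sel_b: AtomSelector,
                         label: str = "") -> DistanceSeries:
    """Euclidean distance between two uniquely selected atoms, per frame.

    Internal distances are invariant under rigid-body motion, so no
    superposition is performed.
    """
    ia = _resolve_single(traj, sel_a)
    ib = _resolve_single(traj, sel_b)
    if ia == ib:
        raise SelectionError("the two selectors resolve to the same atom")
    d = np.linalg.norm(traj.frames[:, ia, :] - traj.frames[:, ib, :], axis=1)
    if not label:
        a, b = traj.topology.atoms[ia], traj.topology.atoms[ib]
        label = f"{a.res_name}{a.res_num}:{b.res_name}{b.res_num}"
    return DistanceSeries(label, traj.times, d)


def hbond_length_series(traj: Trajectory,
                        bonds: Sequence[HBondDefinition],
                        ) -> list[DistanceSeries]:
    """Heavy-atom N···O distance per frame for each bond definition."""
    out = []
    for bond in bonds:
        try:
            i_don = _resolve_single(
                traj, AtomSelector(res_nums=bond.donor[0],
                                   atom_names={bond.donor[1]}))
            i_acc = _resolve_single(
                traj, AtomSelector(res_nums=bond.acceptor[0],
                                   atom_names={bond.acceptor[1]}))
        except SelectionError as exc:
            raise SelectionError(f"bond {bond.label}: {exc}") from exc
        d = np.linalg.norm(traj.frames[:, i_don, :] - traj.frames[:, i_acc, :],
                           axis=1)
        out.append(DistanceSeries(bond.label, traj.times, d))
    return out


def helix_integrity_series(traj: Trajectory,
                           helix_bonds: Sequence[HBondDefinition],
                           threshold: float = HBOND_BREAK_THRESHOLD,
                           ) -> tuple[DistanceSeries, np.ndarray]:
    """Average bond length of a helix's hydrogen bonds per frame.

    Returns the mean-length series and a boolean flag series that is True
    wherever the mean exceeds ``threshold`` (3.5 Angstrom by default),
    implying that one or more bonds are broken.
    """
    if not helix_bonds:
        raise ValueError("helix bond set is empty")
    series = hbond_length_series(traj, helix_bonds)
    stack = np.vstack([s.values for s in series])
    mean = stack.mean(axis=0)
    return DistanceSeries("helix-mean", traj.times, mean), mean > threshold


def detachment_events(series: DistanceSeries, threshold: float,
                      min_duration_ps: float,
                      merge_gap_ps: float | None = None,
                      ) -> list[DetachmentEvent]:
    """Detect maximal above-threshold excursions of a distance series.

    A run of consecutive frames with value > ``threshold`` becomes an
    event if it lasts at least ``min_duration_ps``. Runs separated by a
    below-threshold gap shorter than ``merge_gap_ps`` (default: the
    minimum duration) are merged first, which suppresses flicker at the
    threshold crossing. Durations count frames inclusively, i.e. a run of
    k frames at spacing dt lasts k*dt.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if merge_gap_ps is None:
        merge_gap_ps = min_duration_ps
    above = series.values > threshold
    if series.times.size > 1:
        dt = float(series.times[1] - series.times[0])
    else:
        dt = 1.0
    runs: list[list[int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append([start, i - 1])
            start = None
    if start is not None:
        runs.append([start, len(above) - 1])
    merged: list[list[int]] = []
    for run in runs:
        if merged and (run[0] - merged[-1][1] - 1) * dt < merge_gap_ps:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    events = []
    for s, e in merged:
        if (e - s + 1) * dt >= min_duration_ps:
            events.append(DetachmentEvent(
                series.label,
                float(series.times[s]),
                float(series.times[e]),
                float(series.values[s:e + 1].max()),
            ))
    return events


# --- pre-registered bond sets ---------------------------------------------


def helix_bond_set(first_acceptor: int, last_acceptor: int,
                   offset: int = 4) -> list[HBondDefinition]:
    """i O : (i+offset) N backbone bonds for acceptor residues in a range."""
    return [HBondDefinition(donor=(i + offset, "N"), acceptor=(i, "O"))
            for i in range(first_acceptor, last_acceptor + 1)]


def _beta2a_3a() -> list[HBondDefinition]:
    pairs = [((90, "N"), (172, "O")), ((172, "N"), (90, "O")),
             ((92, "N"), (170, "O")), ((170, "N"), (92, "O")),
             ((94, "N"), (168, "O"))]
    return [HBondDefinition(donor=d, acceptor=a) for d, a in pairs]


#: Named bond sets for the serpin topology in source-structure numbering.
#: helix F starts with a tightened i->i+3 first turn in the crystal, so its
#: set is 128O:131N plus the regular i->i+4 ladder 129O:133N .. 141O:145N.
BOND_SETS: dict[str, list[HBondDefinition]] = {
    "beta2A_3A": _beta2a_3a(),
    "helixD": helix_bond_set(70, 79),
    "helixF": [HBondDefinition(donor=(131, "N"), acceptor=(128, "O"))]
    + helix_bond_set(129, 141),
}

#: Named Cα–Cα distance pairs monitored for loop and gate dynamics.
DISTANCE_PAIRS: dict[str, tuple[int, int]] = {
    "G230:W86": (230, 86),
    "V157:A318": (157, 318),
    "I342:K176": (342, 176),
}

_BOND_LINE = re.compile(
    r"^\s*(-?\d+)\s+(\w+)\s*:\s*(-?\d+)\s+(\w+)\s*(?:#.*)?$"
)


def read_bond_config(path: str | Path) -> list[HBondDefinition]:
    """Read a bond set from a flat text file.

    One bond per line, ``<res> <atom> : <res> <atom>`` (e.g.
    ``172 O : 90 N``); ``#`` starts a comment. The N-side atom is taken as
    the donor and the O-side as the acceptor regardless of order.
    """
    bonds = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            m = _BOND_LINE.match(stripped)
            if not m:
                raise ValueError(f"{path}:{lineno}: cannot parse bond line")
            first = (int(m.group(1)), m.group(2).upper())
            second = (int(m.group(3)), m.group(4).upper())
            if first[1].startswith("N"):
                donor, acceptor = first, second
            else:
                donor, acceptor = second, first
            bonds.append(HBondDefinition(donor=donor, acceptor=acceptor))
    return bonds


def write_series_table(series: Sequence[DistanceSeries], path: str | Path,
                       flags: np.ndarray | None = None) -> None:
    """Write one or more distance series as tidy CSV
    (label, time_ps, value[, flag])."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = ["label", "time_ps", "value"]
        if flags is not None:
            header.append("flag")
        w.writerow(header)
        for s in series:
            for i, (t, v) in enumerate(zip(s.times, s.values)):
                row = [s.label, f"{t:.3f}", f"{v:.6f}"]
                if flags is not None:
                    row.append(int(flags[i]))
                w.writerow(row)
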