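"""Peptide-level HDX-MS uptake processing.

Deuterium uptake is expressed relative to a full-deuteration (FD) control
measured per peptide, which absorbs back-exchange without any intrinsic-rate
correction. Overlapping peptides sharing one terminus can be subtracted to
give "sub-peptide" uptake on the residues unique to the parent — valid only
when the two peptides' back-exchange levels are comparable, so the
subtraction carries a back-exchange deviation guard (default tolerance 8.2
percentage points, with typical deviations near 2.7).

Exchangeable amides follow the standard bottom-up convention: the first two
residues of a peptide and all prolines beyond position 2 do not contribute.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Peptide",
    "UptakeRecord",
    "FullDeuterationControl",
    "SubPeptide",
    "HeatmapTable",
    "HdxWarning",
    "PairingError",
    "ControlLookupError",
    "deuterium_content",
    "max_exchangeable",
    "relative_uptake",
    "backexchange",
    "subpeptide_uptake",
    "select_covering_subset",
    "build_heatmap",
    "uptake_difference",
    "read_uptake_table",
    "write_uptake_table",
    "DEFAULT_LABELING_FRACTION",
    "DEFAULT_BE_TOLERANCE",
    "TYPICAL_BE_DEVIATION",
]

#: Deuterium fraction of the labeling buffer (99% deuterated).
DEFAULT_LABELING_FRACTION = 0.99
#: Default tolerance (percentage points) on the back-exchange deviation
#: between a parent/child pair used for sub-peptide subtraction — the
#: largest deviation observed in the reference dataset.
DEFAULT_BE_TOLERANCE = 8.2
#: Average parent/child back-exchange deviation in the reference dataset,
#: reported for context in warnings.
TYPICAL_BE_DEVIATION = 2.7

_AA = set("ACDEFGHIKLMNPQRSTVWY")


class HdxWarning(UserWarning):
    pass


class PairingError(ValueError):
    pass


class ControlLookupError(KeyError):
    pass


@dataclass(frozen=True)
class Peptide:
    """A proteolytic peptide in protein numbering (inclusive range)."""

    sequence: str
    start_res: int
    end_res: int
    state: str = "active"

    def __post_init__(self):
        if self.end_res < self.start_res:
            raise ValueError("end_res must be >= start_res")
        bad = set(self.sequence.upper()) - _AA
        if bad:
            raise ValueError(f"unknown residue code(s) {sorted(bad)}")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start_res, self.end_res)

    @property
    def residues(self) -> range:
        return range(self.start_res, self.end_res + 1)

    def __len__(self) -> int:
        return self.end_res - self.start_res + 1


@dataclass
class UptakeRecord:
    peptide: Peptide
    timepoint: float            # minutes
    deuterium: float            # Da
    centroid_mass: float | None = None
    replicate_sd: float | None = None

    def __post_init__(self):
        if self.timepoint <= 0:
            raise ValueError("timepoint must be positive (minutes)")
        if self.deuterium < 0:
            raise ValueError("deuterium content must be >= 0")


@dataclass
class FullDeuterationControl:
    peptide: Peptide
    deuterium_fd: float         # Da

    def __post_init__(self):
        if self.deuterium_fd <= 0:
            raise ValueError("FD deuterium must be positive")
        cap = max_exchangeable(self.peptide.sequence)
        if cap and self.deuterium_fd > cap:
            raise ValueError(
                f"FD deuterium {self.deuterium_fd} exceeds the "
                f"{cap} exchangeable amides of {self.peptide.sequence}"
            )


@dataclass
class SubPeptide:
    """Uptake on the residues of a parent peptide not covered by a nested
    child, obtained by per-timepoint subtraction."""

    parent: Peptide
    child: Peptide
    start_res: int
    end_res: int
    sequence: str
    deuterium: dict[float, float]
    be_deviation: float | None = None
    be_flagged: bool = False

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start_res, self.end_res)


def deuterium_content(centroid_t: float, centroid_undeut: float) -> float:
    """Deuterium uptake (Da) as the centroid mass shift, clamped at 0.

    Small negative shifts from replicate noise are clamped to zero with a
    warning rather than treated as errors.
    """
    if centroid_t <= 0 or centroid_undeut <= 0:
        raise ValueError("centroid masses must be positive")
    d = centroid_t - centroid_undeut
    if d < 0:
        warnings.warn(
            f"negative mass shift {d:.4f} Da clamped to 0", HdxWarning,
            stacklevel=2)
        return 0.0
    return d


def max_exchangeable(sequence: str) -> int:
    """Number of exchange-competent backbone amides in a peptide.

    The first two residues (fast back-exchange) and prolines beyond
    position 2 (no amide hydrogen) are excluded; never negative.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"unknown residue code(s) {sorted(bad)}")
    return max(0, len(seq) - 2 - seq[2:].count("P"))


def relative_uptake(record: UptakeRecord,
                    control: FullDeuterationControl) -> float:
    """Deuterium uptake as a fraction of the full-deuteration control."""
    if control.peptide.interval != record.peptide.interval or \
            control.peptide.state != record.peptide.state:
        raise ControlLookupError(
            f"control peptide {control.peptide.interval} does not match "
            f"record peptide {record.peptide.interval}"
        )
    frac = record.deuterium / control.deuterium_fd
    if frac > 1.0:
        warnings.warn(
            f"relative uptake {frac:.3f} exceeds 1 for peptide "
            f"{record.peptide.interval}", HdxWarning, stacklevel=2)
    return frac


def backexchange(peptide: Peptide, control: FullDeuterationControl,
                 labeling_fraction: float = DEFAULT_LABELING_FRACTION,
                 ) -> float:
    """Back-exchange level (percent) inferred from the FD control.

    100 * (1 - D_fd / (L * N_exch)) with labeling fraction L and the
    exchangeable-amide count N_exch.
    """
    n = max_exchangeable(peptide.sequence)
    if n == 0:
        raise ValueError(
            f"peptide {peptide.sequence} has no exchangeable amides; "
            "back-exchange undefined")
    return 100.0 * (1.0 - control.deuterium_fd / (labeling_fraction * n))


def _nested_remainder(parent: Peptide, child: Peptide) -> tuple[int, int]:
    """Residue interval of parent not covered by child; the child must nest
    inside the parent sharing exactly one terminus."""
    if not (parent.start_res <= child.start_res
            and child.end_res <= parent.end_res):
        raise PairingError("child peptide does not nest inside parent")
    shares_start = child.start_res == parent.start_res
    shares_end = child.end_res == parent.end_res
    if shares_start == shares_end:
        raise PairingError(
            "child must share exactly one terminus with the parent")
    if shares_start:
        return (child.end_res + 1, parent.end_res)
    return (parent.start_res, child.start_res - 1)


def subpeptide_uptake(parent_records: Sequence[UptakeRecord],
                      child_records: Sequence[UptakeRecord],
                      parent_control: FullDeuterationControl | None = None,
                      child_control: FullDeuterationControl | None = None,
                      be_tolerance: float = DEFAULT_BE_TOLERANCE,
                      labeling_fraction: float = DEFAULT_LABELING_FRACTION,
                      ) -> SubPeptide:
    """Sub-peptide deuterium content by parent − child subtraction.

    Requires matching timepoints and states. When both FD controls are
    supplied the parent/child back-exchange deviation is computed and the
    result is flagged (with a warning) if it exceeds ``be_tolerance``
    percentage points.
    """
    if not parent_records or not child_records:
        raise PairingError("empty record list")
    parent = parent_records[0].peptide
    child = child_records[0].peptide
    if parent.state != child.state:
        raise PairingError("parent and child are from different states")
    start, end = _nested_remainder(parent, child)
    offset = start - parent.start_res
    seq = parent.sequence[offset:offset + (end - start + 1)]
    p_by_t = {r.timepoint: r.deuterium for r in parent_records}
    c_by_t = {r.timepoint: r.deuterium for r in child_records}
    if set(p_by_t) != set(c_by_t):
        raise PairingError(
            f"timepoint mismatch: parent {sorted(p_by_t)} vs child "
            f"{sorted(c_by_t)}")
    deut = {}
    for t in sorted(p_by_t):
        d = p_by_t[t] - c_by_t[t]
        if d < 0:
            warnings.warn(
                f"sub-peptide {start}-{end} at t={t} min: negative "
                f"difference {d:.4f} Da clamped to 0", HdxWarning,
                stacklevel=2)
            d = 0.0
        deut[t] = d
    be_dev = None
    flagged = False
    if parent_control is not None and child_control is not None:
        be_p = backexchange(parent, parent_control, labeling_fraction)
        be_c = backexchange(child, child_control, labeling_fraction)
        be_dev = abs(be_p - be_c)
        if be_dev > be_tolerance:
            flagged = True
            warnings.warn(
                f"back-exchange deviation {be_dev:.1f} points between "
                f"{parent.interval} and {child.interval} exceeds the "
                f"{be_tolerance} tolerance (typical deviation "
                f"{TYPICAL_BE_DEVIATION})", HdxWarning, stacklevel=2)
    return SubPeptide(parent, child, start, end, seq, deut, be_dev, flagged)


def select_covering_subset(peptides: Sequence[Peptide],
                           weights: Sequence[float] | None = None,
                           target_range: tuple[int, int] | None = None,
                           ) -> tuple[list[Peptide], float]:
    """Greedy weighted set cover over residue intervals.

    Repeatedly picks the peptide adding the largest weighted count of
    still-uncovered residues; ties go to the shorter peptide, then the
    lower start. Returns the chosen subset (in pick order) and the
    fraction of the target range covered. With no explicit target range,
    the union of all input intervals is the target.
    """
    if not peptides:
        return [], 0.0
    if weights is None:
        weights = [1.0] * len(peptides)
    if target_range is None:
        lo = min(p.start_res for p in peptides)
        hi = max(p.end_res for p in peptides)
    else:
        lo, hi = target_range
    target = set(range(lo, hi + 1))
    uncovered = set()
    for p in peptides:
        uncovered |= set(p.residues) & target
    total_target = hi - lo + 1
    chosen: list[Peptide] = []
    remaining = list(zip(peptides, weights))
    while uncovered and remaining:
        best = None
        for k, (p, w) in enumerate(remaining):
            gain = w * len(set(p.residues) & uncovered)
            key = (-gain, len(p), p.start_res)
            if gain > 0 and (best is None or key < best[0]):
                best = (key, k)
        if best is None:
            break
        _, k = best
        p, _ = remaining.pop(k)
        chosen.append(p)
        uncovered -= set(p.residues)
    coverage = len(_covered_set(chosen) & target) / total_target
    return chosen, coverage


def _covered_set(peptides: Iterable[Peptide]) -> set[int]:
    out: set[int] = set()
    for p in peptides:
        out |= set(p.residues)
    return out


@dataclass
class HeatmapTable:
    """Relative-uptake heat map: peptides (rows) x timepoints (columns).

    ``values`` holds relative uptake (NaN for missing cells, never
    dropped); ``classes`` the corresponding color-class index per the
    configured edges (-1 for missing).
    """

    values: pd.DataFrame
    classes: pd.DataFrame
    class_edges: np.ndarray


def _default_edges() -> np.ndarray:
    return np.linspace(0.0, 1.0, 11)  # deciles


def build_heatmap(records: Sequence[UptakeRecord],
                  controls: Mapping[tuple[int, int, str],
                                    FullDeuterationControl],
                  timepoints: Sequence[float] = (1.0, 5.0, 20.0),
                  class_edges: Sequence[float] | None = None,
                  ) -> HeatmapTable:
    """Assemble the relative-uptake heat map table.

    Rows are peptides ordered by start residue (then end residue),
    identified as (state, start, end, sequence); columns are the requested
    timepoints. Cells without a record are explicit NaN.
    """
    edges = np.asarray(class_edges if class_edges is not None
                       else _default_edges(), dtype=float)
    rows: dict[tuple[str, int, int, str], dict[float, float]] = {}
    for r in records:
        key = (r.peptide.state, r.peptide.start_res, r.peptide.end_res,
               r.peptide.sequence)
        ctrl = controls.get((r.peptide.start_res, r.peptide.end_res,
                             r.peptide.state))
        if ctrl is None:
            raise ControlLookupError(
                f"no FD control for peptide {key[1]}-{key[2]} ({key[0]})")
        if r.timepoint in timepoints:
            rows.setdefault(key, {})[r.timepoint] = relative_uptake(r, ctrl)
    index = sorted(rows, key=lambda k: (k[0], k[1], k[2]))
    values = pd.DataFrame(
        [[rows[k].get(t, np.nan) for t in timepoints] for k in index],
        index=pd.MultiIndex.from_tuples(
            index, names=["state", "start", "end", "sequence"]),
        columns=list(timepoints),
    )
    classes = values.map(
        lambda v: -1 if pd.isna(v)
        else int(min(np.searchsorted(edges, v, side="right") - 1,
                     len(edges) - 2)))
    return HeatmapTable(values, classes, edges)


def uptake_difference(active_records: Sequence[UptakeRecord],
                      latent_records: Sequence[UptakeRecord],
                      controls: Mapping[tuple[int, int, str],
                                        FullDeuterationControl],
                      ) -> tuple[pd.DataFrame, list[tuple[int, int]]]:
    """Active − latent relative uptake per peptide per timepoint.

    Peptides present in only one state are excluded and returned in the
    exclusion list rather than silently dropped.
    """
    def table(records: Sequence[UptakeRecord], state: str):
        out: dict[tuple[int, int], dict[float, float]] = {}
        for r in records:
            ctrl = controls.get((r.peptide.start_res, r.peptide.end_res,
                                 state))
            if ctrl is None:
                raise ControlLookupError(
                    f"no FD control for {r.peptide.interval} ({state})")
            out.setdefault(r.peptide.interval, {})[r.timepoint] = \
                relative_uptake(r, ctrl)
        return out

    act = table(active_records, "active")
    lat = table(latent_records, "latent")
    shared = sorted(set(act) & set(lat))
    excluded = sorted(set(act) ^ set(lat))
    timepoints = sorted({t for p in shared
                         for t in set(act[p]) & set(lat[p])})
    data = [[act[p].get(t, np.nan) - lat[p].get(t, np.nan)
             for t in timepoints] for p in shared]
    df = pd.DataFrame(data, index=pd.MultiIndex.from_tuples(
        shared, names=["start", "end"]), columns=timepoints)
    return df, excluded


# --- uptake-table dialect --------------------------------------------------

_COLUMNS = ["sequence", "start", "end", "state", "timepoint_min", "deuterium"]


def read_uptake_table(path: str | Path):
    """Read the delimited uptake-table dialect.

    Columns: sequence, start, end, state, timepoint_min, deuterium
    [, centroid_mass, replicate_sd]. Rows with timepoint_min = "FD" are
    full-deuteration controls. Returns (records, controls) with controls
    keyed by (start, end, state).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"uptake table missing columns {sorted(missing)}")
    records: list[UptakeRecord] = []
    controls: dict[tuple[int, int, str], FullDeuterationControl] = {}
    for _, row in df.iterrows():
        pep = Peptide(str(row["sequence"]), int(row["start"]),
                      int(row["end"]), str(row["state"]))
        if str(row["timepoint_min"]).strip().upper() == "FD":
            controls[(pep.start_res, pep.end_res, pep.state)] = \
                FullDeuterationControl(pep, float(row["deuterium"]))
        else:
            records.append(UptakeRecord(
                pep, float(row["timepoint_min"]), float(row["deuterium"]),
                centroid_mass=(float(row["centroid_mass"])
                               if "centroid_mass" in df.columns
                               and pd.notna(row.get("centroid_mass"))
                               else None),
                replicate_sd=(float(row["replicate_sd"])
                              if "replicate_sd" in df.columns
                              and pd.notna(row.get("replicate_sd"))
                              else None),
            ))
    return records, controls


def write_uptake_table(records: Sequence[UptakeRecord],
                       controls: Mapping[tuple[int, int, str],
                                         FullDeuterationControl],
                       path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_COLUMNS + ["replicate_sd"])
        for r in records:
            w.writerow([r.peptide.sequence, r.peptide.start_res,
                        r.peptide.end_res, r.peptide.state,
                        f"{r.timepoint:g}", f"{r.deuterium:.6f}",
                        "" if r.replicate_sd is None
                        else f"{r.replicate_sd:.6f}"])
        for (start, end, state), c in sorted(controls.items()):
            w.writerow([c.peptide.sequence, start, end, state, "FD",
                        f"{c.deuterium_fd:.6f}", ""])
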