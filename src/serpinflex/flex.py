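"""Superposition and flexibility metrics: Cα-RMSD, Cα-RMSF and binned
per-frame deviation densities.

All superpositions are unweighted least-squares (Kabsch) fits over a
user-chosen fit set; the fit set and the measurement set are independent
parameters so that, e.g., mobile-loop residues can be excluded from an
RMSD report while still contributing to (or being excluded from) the fit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .traj_io import Structure, Trajectory

__all__ = [
    "FlexProfile",
    "DeviationHistogram",
    "DeviationMatrix",
    "FitError",
    "MissingResidueError",
    "superpose",
    "rmsd_series_vs_first",
    "average_structure",
    "rmsf_per_residue",
    "per_frame_residue_deviation",
    "pool_deviations",
    "bin_deviations",
    "replicate_stats",
    "write_profile_csv",
    "write_histogram_csv",
    "write_series_csv",
]


class FitError(ValueError):
    """Degenerate superposition problem (too few or collinear atoms)."""


class MissingResidueError(KeyError):
    def __init__(self, res_nums: Sequence[int]):
        self.res_nums = list(res_nums)
        super().__init__(f"residues without a CA atom: {self.res_nums}")


@dataclass
class FlexProfile:
    """Per-residue flexibility values in Angstrom (RMSF or mean RMSD)."""

    res_nums: list[int]
    values: np.ndarray
    kind: str = "RMSF"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.res_nums) != self.values.shape[0]:
            raise ValueError("res_nums and values must have equal length")
        if np.any(self.values < 0):
            raise ValueError("flexibility values must be non-negative")


@dataclass
class DeviationHistogram:
    """Per-residue histogram of per-frame Cα deviations.

    ``fractions[i, j]`` is the percentage of frames for residue ``i`` whose
    deviation falls in ``[bin_edges[j], bin_edges[j+1])``; rows sum to 100.
    ``means`` carries the per-residue mean deviation.
    """

    res_nums: list[int]
    bin_width: float
    bin_edges: np.ndarray
    fractions: np.ndarray
    means: np.ndarray

    def __post_init__(self) -> None:
        sums = self.fractions.sum(axis=1)
        if not np.allclose(sums, 100.0, atol=1e-9):
            raise ValueError("per-residue fractions must sum to 100%")
        if np.any(self.fractions < 0):
            raise ValueError("fractions must be non-negative")


@dataclass
class DeviationMatrix:
    """(frames x residues) per-frame Cα deviations from the average
    structure, sampled every ``stride_ps`` ps."""

    matrix: np.ndarray
    res_nums: list[int]
    stride_ps: float


# --- superposition ---------------------------------------------------------


def _kabsch_batch(mobile: np.ndarray, reference: np.ndarray):
    """Proper-rotation least-squares fit, batched over leading axes.

    ``mobile`` is (..., n, 3), ``reference`` (n, 3). Returns rotations
    (..., 3, 3), translations (..., 3) such that
    ``x @ R.swapaxes(-1,-2) + t`` best matches the reference.
    """
    cm = mobile.mean(axis=-2, keepdims=True)
    cr = reference.mean(axis=0)
    P = mobile - cm
    Q = reference - cr
    H = np.einsum("...ni,nj->...ij", P, Q)
    U, _, Vt = np.linalg.svd(H)
    # proper rotation: R = V diag(1,1,d) U^T, d = sign(det(V) det(U))
    d = np.sign(np.linalg.det(U @ Vt))
    U = U.copy()
    U[..., :, 2] *= d[..., None]
    R = Vt.swapaxes(-1, -2) @ U.swapaxes(-1, -2)
    t = cr - np.einsum("...ij,...j->...i", R, cm[..., 0, :])
    return R, t


def _check_fit_set(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise FitError("superposition needs at least 3 fit atoms")
    c = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(c, tol=1e-8) < 2:
        raise FitError("fit atoms are collinear or coincident")


def superpose(mobile: np.ndarray, reference: np.ndarray,
              fit_indices: Sequence[int] | None = None):
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` where the transform
    ``x -> rotation @ x + translation`` minimizes the RMSD over the fit
    atoms and the rotation is proper (det +1). ``rmsd`` is reported over
    the fit atoms, in Angstrom.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise FitError("mobile and reference must have equal shapes")
    idx = np.arange(mobile.shape[0]) if fit_indices is None else np.asarray(
        fit_indices, dtype=int)
    _check_fit_set(reference[idx])
    R, t = _kabsch_batch(mobile[idx], reference[idx])
    moved = mobile[idx] @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference[idx]) ** 2, axis=1))))
    return R, t, rmsd


def _superpose_frames(frames: np.ndarray, reference: np.ndarray,
                      fit_indices: np.ndarray) -> np.ndarray:
    """Superpose every frame onto the reference over the fit set (batched)."""
    _check_fit_set(reference[fit_indices])
    R, t = _kabsch_batch(frames[:, fit_indices, :], reference[fit_indices])
    return np.einsum("fij,fnj->fni", R, frames) + t[:, None, :]


def _resolve_fit(traj: Trajectory,
                 fit_indices: Sequence[int] | None) -> np.ndarray:
    if fit_indices is None:
        ca = [i for i, a in enumerate(traj.topology.atoms) if a.name == "CA"]
        return np.asarray(ca if ca else range(traj.topology.n_atoms), dtype=int)
    return np.asarray(fit_indices, dtype=int)


def rmsd_series_vs_first(traj: Trajectory,
                         fit_indices: Sequence[int] | None = None,
                         measure_indices: Sequence[int] | None = None,
                         ) -> np.ndarray:
    """Cα-RMSD of every frame relative to the first frame.

    Each frame is superposed on frame 0 over ``fit_indices`` (default: all
    Cα) and the RMSD is evaluated over ``measure_indices`` (default: the
    fit set), which allows e.g. omitting mobile-loop residues from the
    reported value. ``series[0]`` is exactly 0.
    """
    fit = _resolve_fit(traj, fit_indices)
    measure = fit if measure_indices is None else np.asarray(measure_indices,
                                                             dtype=int)
    ref = traj.frames[0]
    moved = _superpose_frames(traj.frames, ref, fit)
    diff = moved[:, measure, :] - ref[measure]
    out = np.sqrt(np.mean(np.sum(diff ** 2, axis=2), axis=1))
    out[0] = 0.0
    return out


def average_structure(traj: Trajectory,
                      fit_indices: Sequence[int] | None = None) -> np.ndarray:
    """Average coordinates after superposition, two-pass.

    Frames are fit to frame 0 and averaged, then re-fit to that mean and
    averaged once more. Two passes reproduce cpptraj-style averages to
    well below analysis tolerances.
    """
    fit = _resolve_fit(traj, fit_indices)
    mean = _superpose_frames(traj.frames, traj.frames[0], fit).mean(axis=0)
    return _superpose_frames(traj.frames, mean, fit).mean(axis=0)


def _ca_index_map(topology: Structure) -> dict[int, int]:
    return {a.res_num: i for i, a in enumerate(topology.atoms)
            if a.name == "CA"}


def rmsf_per_residue(traj: Trajectory,
                     fit_indices: Sequence[int] | None = None,
                     target_res_nums: Sequence[int] | None = None,
                     ) -> FlexProfile:
    """Per-residue Cα-RMSF about the average structure.

    RMSF_i = sqrt(mean_t |x_i(t) - <x_i>|^2) with every frame superposed
    onto the average structure over the fit set.
    """
    ca = _ca_index_map(traj.topology)
    if target_res_nums is None:
        target_res_nums = sorted(ca)
    missing = [r for r in target_res_nums if r not in ca]
    if missing:
        raise MissingResidueError(missing)
    fit = _resolve_fit(traj, fit_indices)
    avg = average_structure(traj, fit)
    moved = _superpose_frames(traj.frames, avg, fit)
    idx = np.array([ca[r] for r in target_res_nums], dtype=int)
    dev2 = np.sum((moved[:, idx, :] - avg[idx]) ** 2, axis=2)
    return FlexProfile(list(target_res_nums), np.sqrt(dev2.mean(axis=0)),
                       kind="RMSF")


def per_frame_residue_deviation(traj: Trajectory, avg: np.ndarray,
                                stride_ps: float | None = None,
                                fit_indices: Sequence[int] | None = None,
                                ) -> DeviationMatrix:
    """Per-residue, per-frame Cα deviation from the average structure.

    Frames are sampled every ``stride_ps`` ps (default: every frame) and
    globally superposed onto ``avg`` over the fit set; entry (t, i) is the
    Cα displacement norm of residue i in sampled frame t, in Angstrom.
    """
    if stride_ps is None:
        stride_ps = traj.frame_interval
    step_f = stride_ps / traj.frame_interval
    step = int(round(step_f))
    if abs(step_f - step) > 1e-9 or step < 1:
        raise ValueError(
            f"stride {stride_ps} ps is not a multiple of the frame interval "
            f"{traj.frame_interval} ps"
        )
    ca = _ca_index_map(traj.topology)
    res_nums = sorted(ca)
    idx = np.array([ca[r] for r in res_nums], dtype=int)
    fit = _resolve_fit(traj, fit_indices)
    frames = traj.frames[::step]
    moved = _superpose_frames(frames, np.asarray(avg, dtype=float), fit)
    dev = np.linalg.norm(moved[:, idx, :] - np.asarray(avg)[idx], axis=2)
    return DeviationMatrix(dev, res_nums, stride_ps)


def pool_deviations(matrices: Sequence[DeviationMatrix]) -> DeviationMatrix:
    """Concatenate strided deviation matrices from replicate runs."""
    if not matrices:
        raise ValueError("no matrices to pool")
    first = matrices[0]
    for m in matrices[1:]:
        if m.res_nums != first.res_nums or m.stride_ps != first.stride_ps:
            raise ValueError("replicates disagree on residues or stride")
    return DeviationMatrix(np.vstack([m.matrix for m in matrices]),
                           first.res_nums, first.stride_ps)


def bin_deviations(dev: DeviationMatrix | np.ndarray,
                   bin_width: float = 0.1,
                   res_nums: Sequence[int] | None = None,
                   ) -> DeviationHistogram:
    """Histogram per-frame deviations per residue into fixed-width bins.

    Returns percentages per bin (rows sum to 100) and the per-residue mean
    deviation. The default 0.1 Angstrom bin width matches the published
    density-map convention.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if isinstance(dev, DeviationMatrix):
        matrix, res_nums = dev.matrix, dev.res_nums
    else:
        matrix = np.asarray(dev, dtype=float)
        if res_nums is None:
            res_nums = list(range(matrix.shape[1]))
    if matrix.size == 0:
        raise ValueError("empty deviation matrix")
    n_bins = max(1, int(np.floor(matrix.max() / bin_width)) + 1)
    edges = np.arange(n_bins + 1) * bin_width
    n_frames = matrix.shape[0]
    fractions = np.empty((matrix.shape[1], n_bins))
    for i in range(matrix.shape[1]):
        counts, _ = np.histogram(matrix[:, i], bins=edges)
        fractions[i] = counts * (100.0 / n_frames)
    return DeviationHistogram(list(res_nums), bin_width, edges, fractions,
                              matrix.mean(axis=0))


def replicate_stats(profiles: Sequence[FlexProfile],
                    ) -> tuple[FlexProfile, FlexProfile]:
    """Per-residue mean and sample standard deviation across replicates."""
    if not profiles:
        raise ValueError("no profiles")
    res = profiles[0].res_nums
    for p in profiles[1:]:
        if p.res_nums != res:
            raise ValueError("replicate profiles have mismatched residues")
    stack = np.vstack([p.values for p in profiles])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros_like(mean)
    kind = profiles[0].kind
    return (FlexProfile(list(res), mean, kind=kind),
            FlexProfile(list(res), sd, kind=f"{kind}-sd"))


# --- CSV writers -----------------------------------------------------------


def write_profile_csv(profile: FlexProfile, path: str | Path,
                      sd: FlexProfile | None = None) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = ["res_num", profile.kind.lower()]
        if sd is not None:
            header.append("sd")
        w.writerow(header)
        for i, r in enumerate(profile.res_nums):
            row = [r, f"{profile.values[i]:.6f}"]
            if sd is not None:
                row.append(f"{sd.values[i]:.6f}")
            w.writerow(row)


def write_histogram_csv(hist: DeviationHistogram, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["res_num", "bin_lower", "fraction_pct"])
        for i, r in enumerate(hist.res_nums):
            for j in range(hist.fractions.shape[1]):
                w.writerow([r, f"{hist.bin_edges[j]:.3f}",
                            f"{hist.fractions[i, j]:.6f}"])


def write_series_csv(times: np.ndarray, values: np.ndarray,
                     path: str | Path, value_name: str = "value") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_ps", value_name])
        for t, v in zip(times, values):
            w.writerow([f"{t:.3f}", f"{v:.6f}"])
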