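"""Synthetic trajectories and HDX datasets with known ground truth.

The generator is a statistical emulator, not a physical simulation. It
reproduces the statistical structure the analysis stages assume:

* per-residue Gaussian Cα fluctuations of tunable amplitude with AR(1)
  temporal correlation (white noise is the phi = 0 special case, which has
  a closed-form RMSF of sigma * sqrt(3));
* rare two-state large-amplitude excursions of designated residue blocks,
  driven by a two-frame-rate Markov chain (the low-frequency/large-
  amplitude motions seen in loop regions);
* global rigid-body jitter, which superposition must remove exactly;
* peptide-level deuterium uptake from per-residue two-state exchange
  kinetics D_i(t) = L * (1 - exp(-(k_int / PF_i) * t)), with protection
  factors optionally coupled to fluctuation amplitude via
  log10 PF = a - b * sigma, full-deuteration controls, and per-peptide
  back-exchange.

Every generated object is bit-reproducible from its seed; the root seed is
split deterministically per component (coordinates, events, jitter, uptake
noise) so enabling one component never shifts another's random stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import lfilter
from scipy.spatial.transform import Rotation

from .hdx import FullDeuterationControl, Peptide, UptakeRecord, max_exchangeable
from .traj_io import Atom, Structure, Trajectory

__all__ = [
    "Motif",
    "EventBlock",
    "FluctuationSpec",
    "HdxSpec",
    "TrajectoryTruth",
    "HdxTruth",
    "HdxDataset",
    "build_toy_chain",
    "default_motifs",
    "motif_hbonds",
    "chain_sequence",
    "tile_peptides",
    "pf_from_sigma",
    "generate_trajectory",
    "generate_hdx",
]

# 1-letter codes cycled along the toy chain; proline is excluded so every
# residue past a peptide's second position is exchange-competent.
_CYCLE = "ACDEFGHIKLMNQRSTVWY"
_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}
_ONE = {v: k for k, v in _THREE.items()}


@dataclass(frozen=True)
class Motif:
    """A secondary-structure segment: kind in {helix, hairpin, coil},
    starting residue number (chain numbering) and length in residues."""

    kind: str
    start_res: int
    length: int


class LayoutError(ValueError):
    pass


def default_motifs(n_residues: int, start_res: int = 1) -> list[Motif]:
    """Helix + coil + hairpin layout used when none is given."""
    if n_residues < 4:
        raise LayoutError("need at least 4 residues")
    if n_residues < 10:
        return [Motif("coil", start_res, n_residues)]
    if n_residues < 20:
        return [Motif("helix", start_res, n_residues)]
    helix_len = max(10, n_residues // 4)
    hairpin_len = max(8, (n_residues // 4) // 2 * 2 + 2)
    coil1 = (n_residues - helix_len - hairpin_len) // 2
    coil2 = n_residues - helix_len - hairpin_len - coil1
    motifs = [Motif("helix", start_res, helix_len)]
    pos = start_res + helix_len
    if coil1:
        motifs.append(Motif("coil", pos, coil1))
        pos += coil1
    motifs.append(Motif("hairpin", pos, hairpin_len))
    pos += hairpin_len
    if coil2:
        motifs.append(Motif("coil", pos, coil2))
    return motifs


def _helix_ca(length: int) -> np.ndarray:
    i = np.arange(length)
    theta = np.deg2rad(100.0) * i
    return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta),
                            1.5 * i])


def _motif_atoms(motif: Motif, origin: np.ndarray):
    """Return (ca, n, o) coordinate arrays for one motif."""
    L = motif.length
    if motif.kind == "helix":
        if L < 5:
            raise LayoutError("helix needs >= 5 residues for i->i+4 bonds")
        ca = _helix_ca(L) + origin
        n = np.empty_like(ca)
        o = np.empty_like(ca)
        for i in range(L):
            if i + 4 < L:
                u = ca[i + 4] - ca[i]
            else:
                u = ca[L - 1] - ca[L - 5]
            u = u / np.linalg.norm(u)
            o[i] = ca[i] + 1.65 * u
            if i - 4 >= 0:
                w = ca[i] - ca[i - 4]
            else:
                w = ca[4] - ca[0]
            w = w / np.linalg.norm(w)
            n[i] = ca[i] - 1.65 * w
        return ca, n, o
    if motif.kind == "hairpin":
        if L < 6 or L % 2:
            raise LayoutError("hairpin needs an even length >= 6")
        S = (L - 2) // 2
        ca = np.zeros((L, 3))
        # strand 1 along +x, two turn residues, strand 2 antiparallel at
        # y = 4.9 so that O(+1.0 y) ... N(-1.0 y) distances are exactly 2.9
        ca[:S, 0] = 3.3 * np.arange(S)
        ca[S] = [3.3 * S, 1.6, 0.0]
        ca[S + 1] = [3.3 * S, 3.3, 0.0]
        ca[S + 2:, 0] = 3.3 * np.arange(S - 1, -1, -1)
        ca[S + 2:, 1] = 4.9
        ca += origin
        n = ca + np.array([0.3, -1.0, 0.0])
        o = ca + np.array([-0.3, 1.0, 0.0])
        # strand-2 N points down toward strand 1
        n[S + 2:] = ca[S + 2:] + np.array([0.0, -1.0, 0.0])
        o[:S] = ca[:S] + np.array([0.0, 1.0, 0.0])
        return ca, n, o
    if motif.kind == "coil":
        i = np.arange(L)
        ca = np.column_stack([3.5 * i, 0.5 * (-1.0) ** i, np.zeros(L)])
        ca += origin
        return ca, ca + np.array([-0.4, -0.9, 0.3]), ca + np.array(
            [0.5, 0.8, -0.3])
    raise LayoutError(f"unknown motif kind {motif.kind!r}")


def motif_hbonds(motif: Motif) -> list[tuple[tuple[int, str], tuple[int, str]]]:
    """Backbone (donor, acceptor) pairs defined by a motif's construction.

    Helix: i O : i+4 N for every full turn. Hairpin of 2S+2 residues:
    S inter-strand bonds, strand-1 residue j's O to the facing strand-2
    residue's N (residue numbers ``start+L-1-j``).
    """
    r0, L = motif.start_res, motif.length
    if motif.kind == "helix":
        return [((r0 + i + 4, "N"), (r0 + i, "O")) for i in range(L - 4)]
    if motif.kind == "hairpin":
        S = (L - 2) // 2
        return [((r0 + L - 1 - j, "N"), (r0 + j, "O")) for j in range(S)]
    return []


def build_toy_chain(n_residues: int,
                    motifs: Sequence[Motif] | None = None,
                    ca_only: bool = False,
                    chain_id: str = "A",
                    start_res: int = 1) -> Structure:
    """Deterministic toy protein chain with documented geometry.

    Residues carry backbone N, CA and O pseudo-atoms (or CA only) with
    ideal-helix i->i+4 N···O distances near 2.9 Angstrom and exact
    2.9 Angstrom inter-strand hairpin bonds. Motif segments are laid out
    left to right with 12 Angstrom spacing. Residue numbers start at
    ``start_res``; sequence cycles through the 19 non-proline amino acids.
    """
    if n_residues < 4:
        raise LayoutError("need at least 4 residues")
    if motifs is None:
        motifs = default_motifs(n_residues, start_res)
    covered = []
    for m in motifs:
        covered.extend(range(m.start_res, m.start_res + m.length))
    expected = list(range(start_res, start_res + n_residues))
    if covered != expected:
        raise LayoutError(
            "motifs must tile the chain contiguously without overlap")
    atoms: list[Atom] = []
    serial = 1
    x_offset = 0.0
    for m in motifs:
        ca, n, o = _motif_atoms(m, np.array([x_offset, 0.0, 0.0]))
        span = ca[:, 0].max() - min(0.0, ca[:, 0].min())
        x_offset += span + 12.0
        for i in range(m.length):
            res_num = m.start_res + i
            code = _CYCLE[(res_num - start_res) % len(_CYCLE)]
            res_name = _THREE[code]
            if not ca_only:
                atoms.append(Atom(serial, "N", "N", res_name, res_num,
                                  chain_id, n[i]))
                serial += 1
            atoms.append(Atom(serial, "CA", "C", res_name, res_num,
                              chain_id, ca[i]))
            serial += 1
            if not ca_only:
                atoms.append(Atom(serial, "O", "O", res_name, res_num,
                                  chain_id, o[i]))
                serial += 1
    return Structure(atoms, title=f"toy chain n={n_residues}")


def chain_sequence(structure: Structure) -> str:
    """1-letter sequence in residue order (one CA per residue assumed)."""
    return "".join(_ONE[a.res_name] for a in structure.atoms
                   if a.name == "CA")


# --- trajectory generation -------------------------------------------------


@dataclass(frozen=True)
class EventBlock:
    """A residue block undergoing rare two-state excursions.

    The block follows a per-frame Markov chain (closed -> open with
    probability ``p_open``, open -> closed with ``p_close``; stationary
    open fraction p_open / (p_open + p_close)). While open, each residue
    is displaced by ``amplitude * gradient[res] * direction``; the
    optional gradient makes e.g. the upper bonds of a strand open wider
    than the lower ones.
    """

    res_nums: tuple[int, ...]
    amplitude: float            # Angstrom
    direction: tuple[float, float, float] = (0.0, 1.0, 0.0)
    p_open: float = 0.01
    p_close: float = 0.19
    gradient: Mapping[int, float] | None = None

    def __post_init__(self):
        if not (0 <= self.p_open <= 1 and 0 <= self.p_close <= 1):
            raise ValueError("probabilities must be in [0, 1]")

    @property
    def stationary_occupancy(self) -> float:
        denom = self.p_open + self.p_close
        return self.p_open / denom if denom > 0 else 0.0


@dataclass
class FluctuationSpec:
    """Statistical recipe for a synthetic trajectory."""

    sigma: float | np.ndarray = 0.3     # per-axis Gaussian scale, Angstrom
    phi: float = 0.0                    # AR(1) temporal correlation
    rigid_rot_sigma: float = 0.0        # radians, per-frame rotation scale
    rigid_trans_sigma: float = 0.0      # Angstrom, per-frame translation
    events: tuple[EventBlock, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.phi < 1):
            raise ValueError("phi must be in [0, 1)")
        if np.any(np.asarray(self.sigma) < 0):
            raise ValueError("sigma must be >= 0")


@dataclass
class TrajectoryTruth:
    """Generator ground truth for oracle-based checks."""

    res_nums: list[int]
    sigma: np.ndarray                   # per-residue per-axis scale
    event_states: list[np.ndarray]      # one boolean (n_frames,) per block
    event_occupancy: list[float]        # stationary open fractions


def _simulate_chain(rng: np.random.Generator, n_frames: int,
                    p_open: float, p_close: float) -> np.ndarray:
    u = rng.random(n_frames + 1)
    denom = p_open + p_close
    state = np.empty(n_frames, dtype=bool)
    cur = bool(u[0] < (p_open / denom if denom else 0.0))
    for f in range(n_frames):
        if cur:
            cur = not (u[f + 1] < p_close)
        else:
            cur = u[f + 1] < p_open
        state[f] = cur
    return state


def generate_trajectory(structure: Structure, spec: FluctuationSpec,
                        n_frames: int, frame_interval: float = 2.0,
                        ) -> tuple[Trajectory, TrajectoryTruth]:
    """Generate an AR(1)-correlated Gaussian trajectory with events.

    Frame t is ``R_t (X_ref + delta_t + event displacement) + T_t``: the
    per-residue displacement delta is stationary AR(1) with per-axis scale
    sigma and lag-1 correlation phi (applied to all atoms of a residue),
    event blocks add their open-state displacement, and the rigid-body
    jitter (R_t, T_t) is drawn per frame. Identical spec and seed give
    bit-identical output.
    """
    res_nums = structure.res_nums
    n_res = len(res_nums)
    res_index = {r: i for i, r in enumerate(res_nums)}
    atom_res = np.array([res_index[a.res_num] for a in structure.atoms])
    sigma = np.broadcast_to(np.asarray(spec.sigma, dtype=float),
                            (n_res,)).copy()

    ss = np.random.SeedSequence(spec.seed)
    ss_coords, ss_events, ss_jitter = ss.spawn(3)
    rng_c = np.random.default_rng(ss_coords)

    innov_scale = sigma * np.sqrt(1.0 - spec.phi ** 2)
    noise = rng_c.standard_normal((n_frames, n_res, 3)) * \
        innov_scale[None, :, None]
    if spec.phi > 0:
        delta0 = rng_c.standard_normal((n_res, 3)) * sigma[:, None]
        zi = spec.phi * delta0[None]
        delta, _ = lfilter([1.0], [1.0, -spec.phi], noise, axis=0, zi=zi)
    else:
        delta = noise

    states: list[np.ndarray] = []
    occupancy: list[float] = []
    rng_e = np.random.default_rng(ss_events)
    for block in spec.events:
        state = _simulate_chain(rng_e, n_frames, block.p_open, block.p_close)
        states.append(state)
        occupancy.append(block.stationary_occupancy)
        direction = np.asarray(block.direction, dtype=float)
        direction = direction / np.linalg.norm(direction)
        for r in block.res_nums:
            scale = block.amplitude * (
                block.gradient.get(r, 1.0) if block.gradient else 1.0)
            delta[:, res_index[r], :] += \
                state[:, None] * scale * direction[None, :]

    frames = structure.coords[None, :, :] + delta[:, atom_res, :]

    if spec.rigid_rot_sigma > 0 or spec.rigid_trans_sigma > 0:
        rng_j = np.random.default_rng(ss_jitter)
        rotvecs = rng_j.standard_normal((n_frames, 3)) * spec.rigid_rot_sigma
        trans = rng_j.standard_normal((n_frames, 3)) * spec.rigid_trans_sigma
        R = Rotation.from_rotvec(rotvecs).as_matrix()
        center = structure.coords.mean(axis=0)
        frames = np.einsum("fij,fnj->fni", R, frames - center) + center \
            + trans[:, None, :]

    traj = Trajectory(structure, frames, frame_interval)
    return traj, TrajectoryTruth(res_nums, sigma, states, occupancy)


# --- HDX generation --------------------------------------------------------


def tile_peptides(n_residues: int, n_peptides: int = 38,
                  start_res: int = 1) -> list[tuple[int, int]]:
    """Contiguous peptide intervals covering the chain as evenly as
    possible (the reference coverage subset used 38 of them)."""
    if n_peptides < 1 or n_peptides > n_residues // 3:
        raise ValueError("need 1 <= n_peptides <= n_residues / 3")
    bounds = np.linspace(0, n_residues, n_peptides + 1).round().astype(int)
    return [(start_res + bounds[i], start_res + bounds[i + 1] - 1)
            for i in range(n_peptides)]


def pf_from_sigma(sigma: np.ndarray, a: float = 2.0, b: float = 2.0,
                  ) -> np.ndarray:
    """Protection factors monotonically coupled to fluctuation amplitude:
    log10 PF = a - b * sigma, clipped to [0, 8]."""
    return 10.0 ** np.clip(a - b * np.asarray(sigma, dtype=float), 0.0, 8.0)


@dataclass
class HdxSpec:
    """Recipe for a synthetic peptide-level HDX dataset.

    ``k_int`` is the (single, sequence-independent) intrinsic amide
    exchange rate in min^-1; the 10 min^-1 default puts unprotected amides
    on the sub-minute timescale and protected ones on the minute scale.
    Timepoints default to the 0.5–80 min labeling series.
    """

    sequence: str
    start_res: int = 1
    peptides: Sequence[tuple[int, int]] | None = None
    k_int: float = 10.0
    backexchange: float | Sequence[float] = 0.15
    labeling_fraction: float = 0.99
    timepoints: tuple[float, ...] = (0.5, 1, 2, 5, 10, 15, 20, 30, 40, 80)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if np.any(np.asarray(self.backexchange) < 0) or \
                np.any(np.asarray(self.backexchange) >= 1):
            raise ValueError("back-exchange must be in [0, 1)")
        if any(t <= 0 for t in self.timepoints):
            raise ValueError("timepoints must be positive")
        if self.k_int <= 0:
            raise ValueError("k_int must be positive")

    def resolved_peptides(self) -> list[tuple[int, int]]:
        if self.peptides is not None:
            return list(self.peptides)
        return tile_peptides(len(self.sequence),
                             min(38, len(self.sequence) // 3),
                             self.start_res)


@dataclass
class HdxTruth:
    """Per-state ground truth: protection factors, residue-level uptake
    D_i(t), and noise-free peptide deuterium."""

    pf: dict[str, np.ndarray]
    residue_uptake: dict[str, np.ndarray]       # (n_res, n_timepoints)
    peptide_true: dict[str, dict[tuple[int, int], np.ndarray]]
    backexchange: np.ndarray                    # per peptide


@dataclass
class HdxDataset:
    records: list[UptakeRecord]
    controls: dict[tuple[int, int, str], FullDeuterationControl]
    truth: HdxTruth


def generate_hdx(spec: HdxSpec,
                 states: Mapping[str, np.ndarray]) -> HdxDataset:
    """Generate uptake tables, FD controls and ground truth per state.

    ``states`` maps a state name (e.g. "active"/"latent") to a
    per-residue protection-factor array (PF >= 1) aligned with the
    sequence. Residue-level uptake follows two-state exchange kinetics;
    peptide deuterium is the back-exchange-scaled sum over exchangeable
    residues plus Gaussian noise (clamped at 0); the FD control is exact.
    """
    n_res = len(spec.sequence)
    peptides = spec.resolved_peptides()
    be = np.broadcast_to(np.asarray(spec.backexchange, dtype=float),
                         (len(peptides),)).copy()
    lo = spec.start_res
    hi = spec.start_res + n_res - 1
    for start, end in peptides:
        if start < lo or end > hi:
            raise ValueError(
                f"peptide {start}-{end} outside chain {lo}-{hi}")
    t = np.asarray(spec.timepoints, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    pf_maps: dict[str, np.ndarray] = {}
    res_up: dict[str, np.ndarray] = {}
    pep_true: dict[str, dict[tuple[int, int], np.ndarray]] = {}
    records: list[UptakeRecord] = []
    controls: dict[tuple[int, int, str], FullDeuterationControl] = {}

    for state in sorted(states):
        pf = np.asarray(states[state], dtype=float)
        if pf.shape != (n_res,):
            raise ValueError(
                f"PF map for {state!r} must have length {n_res}")
        if np.any(pf < 1):
            raise ValueError("protection factors must be >= 1")
        rate = spec.k_int / pf
        d_res = spec.labeling_fraction * (1.0 - np.exp(-rate[:, None]
                                                       * t[None, :]))
        pf_maps[state] = pf
        res_up[state] = d_res
        pep_true[state] = {}
        for p_idx, (start, end) in enumerate(peptides):
            seq = spec.sequence[start - lo:end - lo + 1]
            pep = Peptide(seq, start, end, state)
            # exchangeable residues: positions 3..L of the peptide,
            # prolines excluded (same rule the analysis applies)
            exch = [i for i in range(start + 2 - lo, end - lo + 1)
                    if spec.sequence[i] != "P"]
            true = (1.0 - be[p_idx]) * d_res[exch, :].sum(axis=0) \
                if exch else np.zeros_like(t)
            pep_true[state][(start, end)] = true
            fd = (1.0 - be[p_idx]) * spec.labeling_fraction * \
                max_exchangeable(seq)
            if fd > 0:
                controls[(start, end, state)] = FullDeuterationControl(
                    pep, fd)
            noise = rng.standard_normal(t.size) * spec.noise_sd \
                if spec.noise_sd > 0 else np.zeros(t.size)
            for j, tp in enumerate(t):
                records.append(UptakeRecord(
                    pep, float(tp), float(max(0.0, true[j] + noise[j])),
                    replicate_sd=spec.noise_sd or None))
    truth = HdxTruth(pf_maps, res_up, pep_true, be)
    return HdxDataset(records, controls, truth)
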