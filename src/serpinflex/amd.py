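"""Dual-boost accelerated-MD parameterization.

Accelerated MD raises energy minima below a threshold by adding a boost
ΔV(V) = (Ethresh − V)² / (α + Ethresh − V) for V < Ethresh, flattening
barriers while preserving the ordering of states. The dual-boost variant
applies one boost to the dihedral energy and one to the total potential.
Thresholds and acceleration parameters follow the standard size-scaled
prescription from average energies of a short conventional run:

    EthreshD = <E_dih> + k · c_res · N_res      alphaD = c_res · N_res / 5
    EthreshP = <E_tot> + k · c_atom · N_atom    alphaP = c_atom · N_atom

with c_res = 3.5 kcal/mol per protein residue, c_atom = 0.16 kcal/mol per
atom, and boost strength k (1 for 1x, 2 for 2x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AmdInputs",
    "AmdBoost",
    "dual_boost_params",
    "boost_energy",
    "format_engine_block",
    "PER_RESIDUE_COEFF",
    "PER_ATOM_COEFF",
]

#: kcal/mol of dihedral boost headroom per protein residue.
PER_RESIDUE_COEFF = 3.5
#: kcal/mol of total-potential boost headroom per atom in the system.
PER_ATOM_COEFF = 0.16


@dataclass(frozen=True)
class AmdInputs:
    """Scalar inputs from a short conventional MD run plus system size."""

    avg_total_potential: float      # kcal/mol
    avg_dihedral_potential: float   # kcal/mol
    n_atoms: int
    n_residues: int
    strength: float = 1.0           # k: 1 = 1x boost, 2 = 2x

    def __post_init__(self):
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be >= 1")
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.n_atoms < self.n_residues:
            raise ValueError("n_atoms must be >= n_residues")
        if not self.strength > 0:
            raise ValueError("boost strength must be positive")


@dataclass(frozen=True)
class AmdBoost:
    """Dual-boost parameters, kcal/mol (full precision; rounding is
    presentation-only)."""

    EthreshD: float
    alphaD: float
    EthreshP: float
    alphaP: float

    def presentation(self) -> dict[str, float]:
        """Values as conventionally printed: total-potential threshold to
        the nearest integer, the rest to one decimal (half away from
        zero)."""
        return {
            "EthreshD": _round_half_away(self.EthreshD, 1),
            "alphaD": _round_half_away(self.alphaD, 1),
            "EthreshP": _round_half_away(self.EthreshP, 0),
            "alphaP": _round_half_away(self.alphaP, 1),
        }


def _round_half_away(x: float, decimals: int) -> float:
    scale = 10 ** decimals
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def dual_boost_params(inputs: AmdInputs,
                      per_residue_coeff: float = PER_RESIDUE_COEFF,
                      per_atom_coeff: float = PER_ATOM_COEFF) -> AmdBoost:
    """Compute dual-boost thresholds and alphas from averages and size.

    Thresholds are linear in the boost strength k with slopes
    ``per_residue_coeff * n_residues`` (dihedral) and
    ``per_atom_coeff * n_atoms`` (total); the alphas are independent of k.
    """
    k = inputs.strength
    dih_span = per_residue_coeff * inputs.n_residues
    tot_span = per_atom_coeff * inputs.n_atoms
    return AmdBoost(
        EthreshD=inputs.avg_dihedral_potential + k * dih_span,
        alphaD=dih_span / 5.0,
        EthreshP=inputs.avg_total_potential + k * tot_span,
        alphaP=tot_span,
    )


def boost_energy(V, Ethresh: float, alpha: float):
    """Boost ΔV added to the potential at energy V (vectorized).

    Zero at and above the threshold, continuous there, and such that
    V + ΔV is monotone non-decreasing in V (state ordering below the
    threshold is compressed, never inverted).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    V = np.asarray(V, dtype=float)
    gap = np.maximum(Ethresh - V, 0.0)
    dv = gap ** 2 / (alpha + gap)
    return dv if dv.ndim else float(dv)


def format_engine_block(boost: AmdBoost, iamd: int = 3) -> str:
    """Presentation-rounded key = value block mirroring an MD-engine
    input section (dual boost: iamd = 3)."""
    p = boost.presentation()

    def fmt(v: float) -> str:
        return f"{v:g}"

    lines = [f"iamd = {iamd}"]
    lines += [f"{k} = {fmt(v)}" for k, v in p.items()]
    return "\n".join(lines)
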