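"""Concordance between per-residue MD flexibility and peptide-level HDX.

Per-residue Cα-RMSF profiles are collapsed to peptide resolution by
averaging over each peptide's residue range, then correlated (Pearson)
against relative deuterium uptake at a chosen timepoint (1 minute by
default). Comparing active−latent *differences* on both axes concentrates
the conformational signal and typically raises the correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .flex import FlexProfile
from .hdx import Peptide

__all__ = [
    "PeptideFlexValue",
    "ConcordanceResult",
    "UndefinedCorrelationError",
    "PeptideCoverageError",
    "peptide_average_rmsf",
    "pearson",
    "concordance",
    "difference_concordance",
    "permutation_pvalue",
    "DEFAULT_COMPARISON_TIMEPOINT",
]

#: Timepoint (minutes) at which uptake is compared with flexibility.
DEFAULT_COMPARISON_TIMEPOINT = 1.0


class UndefinedCorrelationError(ValueError):
    """Raised when either variable has zero variance."""


class PeptideCoverageError(KeyError):
    def __init__(self, intervals):
        self.intervals = list(intervals)
        super().__init__(
            f"peptides with no residues in the profile: {self.intervals}")


@dataclass
class PeptideFlexValue:
    """Mean Cα-RMSF over a peptide's residues, mimicking the
    peptide-resolution of HDX data."""

    peptide: Peptide
    mean_rmsf: float
    n_residues_used: int

    def __post_init__(self):
        if self.mean_rmsf < 0 or self.n_residues_used < 1:
            raise ValueError("invalid peptide flexibility value")


@dataclass
class ConcordanceResult:
    """Pearson rho, sample size, paired table and least-squares trendline."""

    rho: float
    n: int
    table: pd.DataFrame
    slope: float
    intercept: float
    excluded: list[tuple[int, int]]


def peptide_average_rmsf(profile: FlexProfile,
                         peptides: Sequence[Peptide],
                         ) -> list[PeptideFlexValue]:
    """Average a per-residue RMSF profile over each peptide's range.

    Residues absent from the profile are skipped; ``n_residues_used``
    records how many contributed. Peptides with no overlap at all are
    collected into a single error.
    """
    by_res = dict(zip(profile.res_nums, profile.values))
    out: list[PeptideFlexValue] = []
    empty: list[tuple[int, int]] = []
    for pep in peptides:
        vals = [by_res[r] for r in pep.residues if r in by_res]
        if not vals:
            empty.append(pep.interval)
            continue
        out.append(PeptideFlexValue(pep, float(np.mean(vals)), len(vals)))
    if empty:
        raise PeptideCoverageError(empty)
    return out


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; undefined for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def _pair(flex_values: Sequence[PeptideFlexValue],
          uptake: Mapping[tuple[int, int], float]):
    flex_map = {fv.peptide.interval: fv for fv in flex_values}
    shared = sorted(set(flex_map) & set(uptake))
    excluded = sorted(set(flex_map) ^ set(uptake))
    return flex_map, shared, excluded


def concordance(flex_values: Sequence[PeptideFlexValue],
                uptake: Mapping[tuple[int, int], float],
                ) -> ConcordanceResult:
    """Correlate peptide-averaged RMSF with relative uptake.

    ``uptake`` maps (start_res, end_res) to the relative uptake at the
    comparison timepoint. Peptides missing from either side are excluded
    and listed. Returns rho, n, the paired table and the least-squares
    trendline (uptake ~ slope * rmsf + intercept).
    """
    flex_map, shared, excluded = _pair(flex_values, uptake)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} matched peptides; need >= 3")
    x = np.array([flex_map[k].mean_rmsf for k in shared])
    y = np.array([uptake[k] for k in shared])
    rho = pearson(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    table = pd.DataFrame({
        "start": [k[0] for k in shared],
        "end": [k[1] for k in shared],
        "mean_rmsf": x,
        "rel_uptake": y,
        "n_residues_used": [flex_map[k].n_residues_used for k in shared],
    })
    return ConcordanceResult(rho, len(shared), table, float(slope),
                             float(intercept), excluded)


def difference_concordance(active_flex: Sequence[PeptideFlexValue],
                           latent_flex: Sequence[PeptideFlexValue],
                           active_uptake: Mapping[tuple[int, int], float],
                           latent_uptake: Mapping[tuple[int, int], float],
                           ) -> ConcordanceResult:
    """Correlate active−latent differences of RMSF and uptake per peptide.

    Only peptides present in all four inputs participate.
    """
    a_map = {fv.peptide.interval: fv.mean_rmsf for fv in active_flex}
    l_map = {fv.peptide.interval: fv.mean_rmsf for fv in latent_flex}
    keys = set(a_map) & set(l_map) & set(active_uptake) & set(latent_uptake)
    excluded = sorted(
        (set(a_map) | set(l_map) | set(active_uptake) | set(latent_uptake))
        - keys)
    shared = sorted(keys)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} matched peptides; need >= 3")
    dx = np.array([a_map[k] - l_map[k] for k in shared])
    dy = np.array([active_uptake[k] - latent_uptake[k] for k in shared])
    rho = pearson(dx, dy)
    slope, intercept = np.polyfit(dx, dy, 1)
    table = pd.DataFrame({
        "start": [k[0] for k in shared],
        "end": [k[1] for k in shared],
        "delta_rmsf": dx,
        "delta_uptake": dy,
    })
    return ConcordanceResult(rho, len(shared), table, float(slope),
                             float(intercept), excluded)


def permutation_pvalue(x: Sequence[float], y: Sequence[float],
                       n_permutations: int = 1000,
                       seed: int | None = None) -> float:
    """Optional diagnostic (an extension beyond the descriptive rho):
    two-sided permutation p-value for the observed Pearson correlation."""
    rng = np.random.default_rng(seed)
    obs = abs(pearson(x, y))
    y = np.asarray(y, dtype=float)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(y)
        if np.ptp(perm) == 0:
            continue
        if abs(pearson(x, perm)) >= obs:
            hits += 1
    return (hits + 1) / (n_permutations + 1)
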