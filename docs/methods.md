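# Methods

This note documents the models, conventions and numerical choices behind
`serpinflex`, and what the synthetic-data validation does and does not
establish about real data.

## Superposition and flexibility metrics

All fits are unweighted least-squares rigid-body superpositions of Cα
coordinates (Kabsch, via SVD with a determinant correction so the rotation
is always proper; reflections are never returned). Mass weighting is not
used because every metric here is Cα-only. The fit set and the measurement
set are independent parameters throughout: a whole-molecule fit with a
loop excluded from the reported RMSD is a single call. The default fit set
is all Cα atoms, including mobile loops; excluding the RCL (or anything
else) from the fit is the caller's choice via `fit_indices`.

Degenerate fits (fewer than three atoms, or collinear/coincident fit
atoms, rank < 2 with tolerance 1e-8) raise rather than returning an
arbitrary rotation.

The average structure is computed in two passes: superpose all frames on
frame 0 and average, then re-superpose all frames on that mean and average
once more. Full iteration to convergence changes the result by less than
the tolerances of any downstream test, and two passes keep the cost at two
batched SVD sweeps. The average lives in the first frame's orientation;
comparisons against an external reference should superpose once more.

RMSF is defined against the average structure:
`RMSF_i = sqrt(mean_t |x_i(t) − <x_i>|²)` with frames fitted to the
average. By construction `RMSF_i²` equals the mean of the squared
per-frame deviations returned by `per_frame_residue_deviation` when both
use the same fit set (a test asserts agreement at 1e-9 relative).

Per-frame deviation densities use fixed-width bins (default 0.1 Å, the
convention for this kind of density map) with per-residue fractions in
percent summing to 100. Replicate runs are pooled by concatenating strided
frames, so four 1-µs runs written every 2 ps and strided at 200 ps yield
20000 pooled analysis frames. Replicate profile aggregation reports the
per-residue mean and the sample standard deviation (ddof = 1).

## Contact geometry

Hydrogen bonds are measured as heavy-atom backbone N···O distances; no
hydrogens and no angle criterion. This matches the Cα-level resolution of
the trajectories being analyzed and keeps the metric defined for
topologies without protons. Helix integrity is the per-frame arithmetic
mean of a helix's bond lengths; since intact backbone hydrogen bonds are
shorter than 3.5 Å, a mean above 3.5 Å implies at least one broken bond,
and that is the default breakage flag.

Event detection operates on any distance series: maximal runs above a
threshold become events if they last at least `min_duration` (default
1 ns); runs separated by a below-threshold gap shorter than the merge gap
(default: equal to `min_duration`) are merged first, which suppresses
flicker at the threshold crossing. Durations count frames inclusively
(a run of k frames at spacing dt lasts k·dt). The per-bond breakage
threshold reuses 3.5 Å by default because no separate per-bond value is
established; both threshold and duration are exposed as flags.

Pre-registered bond sets use source-structure numbering: the β2A–β3A
ladder {172O:90N, 90O:172N, 170O:92N, 92O:170N, 168O:94N}, helix D
(70O:74N … 79O:83N, ten i→i+4 bonds) and helix F, whose first crystal
turn is tightened: 128O:131N (i→i+3) followed by the regular i→i+4 ladder
129O:133N … 141O:145N. The β3A–β5A pairing is not shipped as a preset;
users supply it through the bond-config file format rather than the
package guessing residue pairs.

## HDX-MS processing

Exchangeable amides per peptide follow the standard bottom-up convention:
`N_exch = length − 2 − (prolines beyond position 2)`, floored at zero. The
first two residues are excluded for their fast back-exchange; prolines
have no amide hydrogen.

Relative uptake is deuterium content divided by the peptide's
full-deuteration control. This single normalization absorbs back-exchange;
no intrinsic-rate (sequence-dependent) correction is applied, and none is
needed as long as comparisons are within-peptide or FD-normalized.
Back-exchange itself is inferred from the FD control as
`100·(1 − D_FD/(L·N_exch))` with labeling fraction L = 0.99 (99 %
deuterated buffer).

Sub-peptides subtract a nested child peptide's deuterium from its parent
per timepoint; the child must share exactly one terminus with the parent.
The subtraction is only meaningful when the two peptides back-exchange
comparably, so the parent/child deviation is computed whenever both FD
controls are available and the result is flagged (with a warning) above a
tolerance of 8.2 percentage points — the largest deviation observed in the
reference dataset, whose average was 2.7 — and both numbers are exposed as
configuration. Negative deuterium (replicate noise) is clamped to zero
with a warning rather than an error, here and in centroid-shift
computation.

Coverage subsets use a greedy weighted interval cover: repeatedly take the
peptide adding the most uncovered residues (ties: shorter peptide, then
lower start). Greedy continues until no peptide adds coverage, so it
always reaches the union of the supplied intervals; the weights allow
preferring higher-quality peptides among equal gains.

Heat-map tables index rows by (state, start, end, sequence) sorted by
start residue, columns by timepoint (default 1, 5, 20 min); missing cells
are explicit NaN, never dropped. Color classes are configurable bin edges
with decile defaults, since no canonical numeric class boundaries exist
for such maps.

## MD↔HDX concordance

Per-residue RMSF is collapsed to peptide resolution by an unweighted mean
over each peptide's residues (residues missing from the profile are
skipped and counted in `n_residues_used`). Concordance is the Pearson
correlation between peptide-averaged RMSF and relative uptake at one
timepoint — 1 min by default, early enough that uptake still
discriminates protection. The paired table, sample size and least-squares
trendline are always reported alongside ρ, and unmatched peptides are
listed rather than silently dropped. Sub-peptides participate as
first-class intervals keyed by (start, end, state). The difference mode
correlates active−latent differences of both quantities over peptides
present in all four inputs; differencing removes the shared baseline and
concentrates the conformational signal. Only descriptive ρ is reported;
an optional permutation p-value is offered as a clearly labeled diagnostic
extension, not part of the core procedure.

## Accelerated-MD parameterization

Dual-boost parameters derive from the average total and dihedral
potential energies of a short conventional run plus system size:

    EthreshD = <E_dih> + k · 3.5 · N_res        alphaD = 3.5 · N_res / 5
    EthreshP = <E_tot> + k · 0.16 · N_atoms     alphaP = 0.16 · N_atoms

with k the boost strength (1 or 2). The 3.5 kcal/mol-per-residue and
0.16 kcal/mol-per-atom coefficients are the standard prescription and are
exposed as configuration. Full-precision values are kept internally;
presentation rounds half-away-from-zero, total-potential thresholds to the
nearest integer and the remaining parameters to one decimal, matching how
such parameter blocks are conventionally printed. The boost
`ΔV = (Ethresh − V)²/(α + Ethresh − V)` for V < Ethresh is zero at and
above the threshold, continuous there, and leaves `V + ΔV` monotone
non-decreasing, so the ordering of states below the threshold is
compressed but never inverted.

## Synthetic-data generator

The generator is a statistical emulator, not a physical simulation: no
force field, no solvent, no thermodynamics. It reproduces the statistical
structure the analyses assume, with full ground truth for oracles.

Trajectories: frame t is `R_t(X_ref + δ_t + event displacement) + T_t`.
The per-residue displacement δ is stationary AR(1) per axis with scale σ_i
and lag-1 correlation φ (white noise, φ = 0, is the special case with the
closed-form RMSF σ√3 used in tests); all atoms of a residue move together.
Event blocks follow a two-state Markov chain (open/close probabilities per
frame, stationary occupancy p_open/(p_open + p_close)) and displace their
residues along a fixed unit direction, optionally with a per-residue
gradient so designated bonds open progressively. Rigid-body jitter draws a
small rotation (rotation-vector scale in radians) and translation per
frame; superposition must remove it exactly, which is itself a test. The
root seed is split deterministically per component (coordinates, events,
jitter) so enabling one component never shifts another's stream; identical
specs and seeds are bit-reproducible.

The toy chain provides deterministic geometry the contact analyses can
interrogate: ideal α-helix Cα traces with pseudo-backbone N/O placed so
i→i+4 N···O distances are ~2.9 Å, and two-strand hairpins with exact
2.9 Å inter-strand bonds (a hairpin of 2S+2 residues defines S bonds). The
sequence cycles the 19 non-proline amino acids so every residue past a
peptide's second position is exchange-competent.

HDX: residue-level uptake follows two-state exchange kinetics
`D_i(t) = L(1 − exp(−(k_int/PF_i)t))` with a single sequence-independent
intrinsic rate (default k_int = 10 min⁻¹, putting unprotected amides on
the sub-minute scale and protected ones on the minute scale that the
experiments resolve at low temperature). Protection couples to flexibility
via `log10 PF = a − b·σ` clipped to [0, 8] (defaults a = 2, b = 2 per Å).
Peptide deuterium is the back-exchange-scaled sum over exchangeable
residues plus Gaussian noise (default sd 0.05 Da, triplicate-scale),
clamped at zero; FD controls are exact:
`D_FD = (1 − BE)·L·N_exch` with default back-exchange 0.15 and labeling
fraction 0.99. Timepoints default to the 0.5–80 min series.

What passing tests show — and do not. The generator guarantees the
*statistical* relationships the pipeline must recover: RMSF ordering
follows σ, histogram mass follows event occupancy, sub-peptide additivity
is exact in the noise-free equal-back-exchange limit, and concordance
recovers a built-in coupling (ρ > 0.5 at 38 peptides and 10⁴ frames in
≥95 of 100 seeded replicates, against a shuffled null below 0.4). It does
not emulate force-field physics, correlated inter-residue motions beyond
the block events, sequence-dependent intrinsic exchange, EX1 behavior, or
peptide misassignment — so correlation magnitudes observed on real
protein data are not predicted by these tests, only the correctness of the
computations applied to such data.

## Problem sizes and numerical conventions

Tests run at deliberately chosen desk scales: frame-accounting uses four
full 500000-frame runs (small chains) since it is exact bookkeeping;
statistical recoveries use 5000–10000 frames, where the closed-form and
3σ bands quoted above apply; the 100-replicate concordance study uses the
reference's 379 residues and 38 peptides. All coordinates are Å, times ps,
timepoints minutes, energies kcal/mol. CSV is the output contract; values
are written at full precision (6 decimals) and rounding happens only at
presentation. Ties and degenerate inputs: altloc resolution keeps the
highest occupancy (ties prefer altloc "A"), insertion codes are rejected,
residue numbers are taken verbatim from the input file (signed), empty
selections are errors rather than empty results, and constant inputs make
correlation an explicit error rather than NaN.
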