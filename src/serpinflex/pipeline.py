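"""Config-driven end-to-end pipeline orchestration.

A run config (YAML or dict) names the stages to execute and their
parameters; ``run_pipeline`` executes them in dependency order, writes all
outputs under one directory and finishes with a manifest that lists every
file written (with SHA-256 hashes) and the fully resolved config, so a
re-run with identical inputs and seeds is byte-reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import amd, compare, flex, hdx, synthetic
from .traj_io import read_pdb

__all__ = ["RunConfig", "ConfigError", "StageError", "run_pipeline",
           "load_config"]

_STAGES = ("simulate_traj", "rmsd", "rmsf", "bins", "simulate_hdx",
           "hdx_heatmap", "compare", "amd_params")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "n_residues": 100,
    "n_frames": 2000,
    "frame_interval_ps": 2.0,
    "sigma_base": 0.2,
    "sigma_span": 0.5,
    "latent_scale": 0.6,
    "stride_ps": 200.0,
    "bin_width": 0.1,
    "n_peptides": 12,
    "timepoints": [1.0, 5.0, 20.0],
    "comparison_timepoint": 1.0,
    "coupling_a": 2.0,
    "coupling_b": 2.0,
    "noise_sd": 0.02,
    "topology_pdb": None,
    "amd": None,
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    stages: list[str]
    outdir: Path
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")
        if not self.stages:
            raise ConfigError("no stages requested")
        merged = dict(_DEFAULTS)
        merged.update(self.params)
        extra = set(self.params) - set(_DEFAULTS)
        if extra:
            raise ConfigError(f"unknown parameters {sorted(extra)}")
        if merged["n_frames"] < 1 or merged["n_residues"] < 4:
            raise ConfigError("n_frames >= 1 and n_residues >= 4 required")
        if merged["bin_width"] <= 0 or merged["stride_ps"] <= 0:
            raise ConfigError("bin_width and stride_ps must be positive")
        pdb = merged.get("topology_pdb")
        if pdb is not None and not Path(pdb).exists():
            raise ConfigError(f"topology_pdb {pdb} does not exist")
        self.params = merged


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    stages = raw.pop("stages", [])
    outdir = Path(raw.pop("outdir", "serpinflex-out"))
    return RunConfig(list(stages), outdir, raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _sigma_profile(n_res: int, base: float, span: float) -> np.ndarray:
    r = np.arange(n_res)
    return base + span * np.abs(np.sin(r / 17.0)) ** 2


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages and write a manifest.

    Returns the manifest dict. On a stage failure the partial outputs are
    retained, the manifest marks the failing stage, and a
    :class:`StageError` is raised.
    """
    p = config.params
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    manifest: dict[str, Any] = {
        "config": {**{k: (str(v) if isinstance(v, Path) else v)
                      for k, v in p.items()},
                   "stages": config.stages, "outdir": str(outdir)},
        "outputs": [],
        "status": "ok",
        "failed_stage": None,
    }
    state: dict[str, Any] = {}
    try:
        for stage in config.stages:
            _run_stage(stage, p, outdir, outputs, state)
    except Exception as exc:
        manifest["status"] = "failed"
        stage = getattr(exc, "stage", stage)
        manifest["failed_stage"] = stage
        _finish_manifest(manifest, outputs, outdir)
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
    _finish_manifest(manifest, outputs, outdir)
    return manifest


def _finish_manifest(manifest: dict[str, Any], outputs: list[Path],
                     outdir: Path) -> None:
    manifest["outputs"] = [
        {"path": str(f.relative_to(outdir)), "sha256": _sha256(f)}
        for f in outputs]
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _require(state: dict[str, Any], key: str, stage: str):
    if key not in state:
        raise StageError(stage, RuntimeError(
            f"requires stage producing {key!r} to run first"))
    return state[key]


def _run_stage(stage: str, p: dict[str, Any], outdir: Path,
               outputs: list[Path], state: dict[str, Any]) -> None:
    try:
        if stage == "simulate_traj":
            if p["topology_pdb"] is not None:
                structure = read_pdb(p["topology_pdb"])
            else:
                structure = synthetic.build_toy_chain(
                    p["n_residues"], ca_only=True)
            n_res = len(structure.res_nums)
            sigma_a = _sigma_profile(n_res, p["sigma_base"], p["sigma_span"])
            specs = {
                "active": sigma_a,
                "latent": p["sigma_base"] + p["latent_scale"] * (
                    sigma_a - p["sigma_base"]),
            }
            state["structure"] = structure
            state["sigma"] = specs
            state["trajs"] = {}
            for name, sigma in specs.items():
                fspec = synthetic.FluctuationSpec(
                    sigma=sigma, seed=p["seed"] + (0 if name == "active"
                                                   else 1))
                traj, truth = synthetic.generate_trajectory(
                    structure, fspec, p["n_frames"], p["frame_interval_ps"])
                state["trajs"][name] = (traj, truth)
        elif stage == "rmsd":
            trajs = _require(state, "trajs", stage)
            for name, (traj, _) in trajs.items():
                series = flex.rmsd_series_vs_first(traj)
                f = outdir / f"rmsd_{name}.csv"
                flex.write_series_csv(traj.times, series, f, "rmsd_A")
                outputs.append(f)
        elif stage == "rmsf":
            trajs = _require(state, "trajs", stage)
            state["profiles"] = {}
            for name, (traj, _) in trajs.items():
                profile = flex.rmsf_per_residue(traj)
                state["profiles"][name] = profile
                f = outdir / f"rmsf_{name}.csv"
                flex.write_profile_csv(profile, f)
                outputs.append(f)
        elif stage == "bins":
            trajs = _require(state, "trajs", stage)
            for name, (traj, _) in trajs.items():
                avg = flex.average_structure(traj)
                stride = p["stride_ps"]
                # fall back to every frame when the requested stride does
                # not fit the trajectory
                if stride > traj.n_frames * traj.frame_interval or \
                        (stride / traj.frame_interval) % 1 > 1e-9:
                    stride = traj.frame_interval
                dev = flex.per_frame_residue_deviation(
                    traj, avg, stride_ps=stride)
                hist = flex.bin_deviations(dev, p["bin_width"])
                f = outdir / f"bins_{name}.csv"
                flex.write_histogram_csv(hist, f)
                outputs.append(f)
        elif stage == "simulate_hdx":
            structure = _require(state, "structure", stage)
            sigma = _require(state, "sigma", stage)
            seq = synthetic.chain_sequence(structure)
            start = structure.res_nums[0]
            peptides = synthetic.tile_peptides(
                len(seq), p["n_peptides"], start)
            spec = synthetic.HdxSpec(
                sequence=seq, start_res=start, peptides=peptides,
                timepoints=tuple(p["timepoints"]),
                noise_sd=p["noise_sd"], seed=p["seed"] + 100)
            pf = {name: synthetic.pf_from_sigma(
                s, p["coupling_a"], p["coupling_b"])
                for name, s in sigma.items()}
            dataset = synthetic.generate_hdx(spec, pf)
            state["hdx"] = dataset
            f = outdir / "uptake_table.csv"
            hdx.write_uptake_table(dataset.records, dataset.controls, f)
            outputs.append(f)
        elif stage == "hdx_heatmap":
            dataset = _require(state, "hdx", stage)
            table = hdx.build_heatmap(dataset.records, dataset.controls,
                                      timepoints=p["timepoints"])
            f = outdir / "heatmap.csv"
            table.values.to_csv(f)
            outputs.append(f)
        elif stage == "compare":
            dataset = _require(state, "hdx", stage)
            profiles = _require(state, "profiles", stage)
            tp = p["comparison_timepoint"]
            for name in sorted(profiles):
                pep_objs = [r.peptide for r in dataset.records
                            if r.peptide.state == name
                            and r.timepoint == tp]
                flex_vals = compare.peptide_average_rmsf(
                    profiles[name], pep_objs)
                uptake = {}
                for r in dataset.records:
                    if r.peptide.state == name and r.timepoint == tp:
                        ctrl = dataset.controls[
                            (r.peptide.start_res, r.peptide.end_res, name)]
                        uptake[r.peptide.interval] = hdx.relative_uptake(
                            r, ctrl)
                result = compare.concordance(flex_vals, uptake)
                f = outdir / f"concordance_{name}.csv"
                with open(f, "w") as fh:
                    fh.write(f"# rho = {result.rho:.6f}, n = {result.n}, "
                             f"slope = {result.slope:.6f}, intercept = "
                             f"{result.intercept:.6f}\n")
                    result.table.to_csv(fh, index=False)
                outputs.append(f)
        elif stage == "amd_params":
            cfg = p.get("amd")
            if not cfg:
                raise ConfigError("amd_params stage needs an 'amd' mapping "
                                  "(etot, edih, natoms, nres[, strength])")
            inputs = amd.AmdInputs(
                avg_total_potential=float(cfg["etot"]),
                avg_dihedral_potential=float(cfg["edih"]),
                n_atoms=int(cfg["natoms"]),
                n_residues=int(cfg["nres"]),
                strength=float(cfg.get("strength", 1.0)))
            boost = amd.dual_boost_params(inputs)
            f = outdir / "amd_params.txt"
            f.write_text(amd.format_engine_block(boost) + "\n")
            outputs.append(f)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc
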