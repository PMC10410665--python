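"""Config-driven orchestration: read -> window -> rdf/KBI -> beta -> contacts
-> density -> descriptors, with TSV outputs and a JSON report.

The config is a YAML mapping with a versioned ``schema`` key.  Validation is
aggregated: every problem found is reported in one error.  Stages run
independently; a failing stage is recorded as failed in the report and the
remaining stages still execute.  With a fixed seed and config the whole run
is deterministic (the report contains no timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .coordinates import read_coordinates
from .kbi import (compute_rdf, finite_size_corrected_rdf, kbi_plateau,
                  kbi_running, write_rdf_tsv)
from .observables import density_profile, descriptor_series
from .preferential import beta_profile, contact_occupancy, occupancy_by_class
from .structure import Trajectory, analysis_window
from . import synthetic

log = logging.getLogger("cosolvkb")


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid config:\n  - " + "\n  - ".join(self.problems))


_DEFAULT_ANALYSES = {
    "rdf": {"dr": 0.02, "r_max": None, "pairs": [["solute", "solute"]],
            "normalization": "open", "corrected": True,
            "plateau_window": None},
    "beta": {"dr": 0.02, "r_max": None, "report_radii": [0.3, 0.5, 1.0]},
    "contacts": {"cutoff": 0.3},
    "density": {"axis": "z", "dz": 0.1, "selections": ["solute", "solvent"]},
    "descriptors": {"probe": 0.14, "n_sphere_points": 960},
}

_TOP_KEYS = {"schema", "input", "generator", "seed", "window_fraction",
             "selections", "analyses", "output_dir"}

_GENERATORS = {
    "ideal_mixture": synthetic.gen_ideal_mixture,
    "lj_fluid": synthetic.gen_lj_fluid,
    "shell_protein": synthetic.gen_shell_protein,
    "slab": synthetic.gen_slab,
}


@dataclass
class PipelineConfig:
    input: dict | None
    generator: dict | None
    selections: dict
    analyses: dict
    window_fraction: float = 0.8
    seed: int = 0
    output_dir: str = "cosolvkb_out"
    raw: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    stages: dict
    summary: dict
    provenance: dict

    def to_json(self) -> str:
        return json.dumps({"stages": self.stages, "summary": self.summary,
                           "provenance": self.provenance},
                          indent=2, sort_keys=True, default=str)


def validate_config(raw) -> PipelineConfig:
    """Type-check and default a raw config (YAML text or mapping)."""
    if isinstance(raw, (str, bytes)):
        raw = yaml.safe_load(raw)
    problems = []
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping"])
    unknown = set(raw) - _TOP_KEYS
    for k in sorted(unknown):
        problems.append(f"unknown key {k!r}")
    if raw.get("schema", 1) != 1:
        problems.append(f"unsupported schema version {raw.get('schema')!r}")
    has_input = "input" in raw
    has_gen = "generator" in raw
    if has_input == has_gen:
        problems.append("exactly one of 'input' or 'generator' is required")
    if has_input and not isinstance(raw.get("input"), dict):
        problems.append("'input' must be a mapping with a 'path'")
    elif has_input and "path" not in raw["input"]:
        problems.append("'input' needs a 'path'")
    if has_gen:
        gen = raw.get("generator")
        if not isinstance(gen, dict) or "kind" not in gen:
            problems.append("'generator' must be a mapping with a 'kind'")
        elif gen["kind"] not in _GENERATORS:
            problems.append(f"unknown generator kind {gen['kind']!r}")
    wf = raw.get("window_fraction", 0.8)
    if not isinstance(wf, (int, float)) or not 0 < wf <= 1:
        problems.append(f"window_fraction {wf!r} outside (0, 1]")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        problems.append(f"seed must be an integer, got {seed!r}")
    sels = raw.get("selections", {"protein": "protein", "solute": "tba",
                                  "solvent": "water"})
    if not isinstance(sels, dict):
        problems.append("'selections' must be a mapping")
        sels = {}
    for name, spec in sels.items():
        if not isinstance(spec, (str, list)):
            problems.append(
                f"selection {name!r} must be a species tag or residue list")
    analyses = {}
    raw_an = raw.get("analyses", {k: {} for k in _DEFAULT_ANALYSES})
    if not isinstance(raw_an, dict):
        problems.append("'analyses' must be a mapping")
        raw_an = {}
    for stage, opts in raw_an.items():
        if stage not in _DEFAULT_ANALYSES:
            problems.append(f"unknown analysis stage {stage!r}")
            continue
        if opts is None:
            opts = {}
        bad = set(opts) - set(_DEFAULT_ANALYSES[stage])
        for k in sorted(bad):
            problems.append(f"unknown key {k!r} in analyses.{stage}")
        merged = {**_DEFAULT_ANALYSES[stage], **opts}
        analyses[stage] = merged
    for key, stage in (("dr", "rdf"), ("dr", "beta"), ("cutoff", "contacts"),
                       ("dz", "density"), ("probe", "descriptors")):
        if stage in analyses:
            v = analyses[stage][key]
            if not isinstance(v, (int, float)) or v <= 0:
                problems.append(f"analyses.{stage}.{key} must be positive, "
                                f"got {v!r}")
    # selection references
    def _check_ref(name, where):
        if name not in sels:
            problems.append(f"{where} references undefined selection "
                            f"{name!r}")
    if "rdf" in analyses:
        for pair in analyses["rdf"]["pairs"]:
            if not (isinstance(pair, (list, tuple)) and len(pair) == 2):
                problems.append("analyses.rdf.pairs entries must be pairs")
                continue
            for nm in pair:
                _check_ref(nm, "analyses.rdf.pairs")
    if "beta" in analyses or "contacts" in analyses:
        for nm in ("protein", "solute", "solvent"):
            _check_ref(nm, "analyses.beta/contacts")
    if "density" in analyses:
        for nm in analyses["density"]["selections"]:
            _check_ref(nm, "analyses.density.selections")
    if "descriptors" in analyses:
        _check_ref("protein", "analyses.descriptors")
    if len(sels) != len({n.lower() for n in sels}):
        problems.append("duplicate selection names")
    if problems:
        raise ConfigError(problems)
    return PipelineConfig(
        input=raw.get("input"), generator=raw.get("generator"),
        selections=sels, analyses=analyses, window_fraction=float(wf),
        seed=seed, output_dir=str(raw.get("output_dir", "cosolvkb_out")),
        raw=raw)


def _resolve(traj: Trajectory, spec):
    if isinstance(spec, str):
        return traj.select(species=spec)
    return traj.select(residue_names=spec)


def _load_trajectory(cfg: PipelineConfig) -> Trajectory:
    if cfg.input is not None:
        return read_coordinates(cfg.input["path"],
                                cfg.input.get("format"))
    gen = dict(cfg.generator)
    kind = gen.pop("kind")
    gen.setdefault("seed", cfg.seed)
    return _GENERATORS[kind](**gen)


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Run every enabled stage and write outputs under ``output_dir``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    traj = _load_trajectory(config)
    traj = analysis_window(traj, config.window_fraction)
    sels = {name: _resolve(traj, spec)
            for name, spec in config.selections.items()}
    stages, summary = {}, {}

    def _run(stage, fn):
        if stage not in config.analyses:
            return
        log.info("running stage %s", stage)
        try:
            fn(config.analyses[stage])
            stages[stage].setdefault("status", "ok")
        except Exception as exc:  # noqa: BLE001 - report and continue
            log.warning("stage %s failed: %s", stage, exc)
            stages[stage] = {"status": "failed", "error": str(exc)}

    def _stage_rdf(opts):
        stages["rdf"] = {"outputs": []}
        for a, b in opts["pairs"]:
            rdf = compute_rdf(traj, sels[a], sels[b], r_max=opts["r_max"],
                              dr=opts["dr"],
                              normalization=opts["normalization"])
            corr = finite_size_corrected_rdf(rdf) if opts["corrected"] \
                else None
            curve = kbi_running(corr if corr is not None else rdf)
            window = opts["plateau_window"]
            if window is None:
                window = (min(1.5, 0.75 * curve.R[-1]), curve.R[-1])
            curve = kbi_plateau(curve, tuple(window))
            path = outdir / f"rdf_{a}_{b}.tsv"
            write_rdf_tsv(path, rdf, corrected=corr, kbi=curve,
                          header_extra=f"pair={a}-{b}")
            stages["rdf"]["outputs"].append(str(path))
            summary[f"kbi_plateau_{a}_{b}_nm3"] = curve.plateau
            summary[f"kbi_plateau_std_{a}_{b}_nm3"] = curve.plateau_std

    def _stage_beta(opts):
        stages["beta"] = {"outputs": []}
        prof = beta_profile(traj, sels["protein"], sels["solute"],
                            sels["solvent"], dr=opts["dr"],
                            r_max=opts["r_max"])
        path = outdir / "beta.tsv"
        with open(path, "w") as fh:
            fh.write("# beta profile (distance from protein surface)\n")
            fh.write("r_nm\tbeta\tn_solute\tn_solvent\n")
            for row in zip(prof.r, prof.beta, prof.n_solute_r,
                           prof.n_solvent_r):
                fh.write("\t".join(f"{v:.8g}" for v in row) + "\n")
        stages["beta"]["outputs"].append(str(path))
        for radius in opts["report_radii"]:
            summary[f"beta_at_{radius}_nm"] = prof.at(radius)

    def _stage_contacts(opts):
        stages["contacts"] = {"outputs": []}
        table = contact_occupancy(traj, sels["solute"], sels["protein"],
                                  cutoff=opts["cutoff"])
        classes = occupancy_by_class(table)
        path = outdir / "contacts.tsv"
        table.to_csv(path, sep="\t", index=False)
        cpath = outdir / "contact_classes.tsv"
        classes.to_csv(cpath, sep="\t", index=False)
        stages["contacts"]["outputs"] += [str(path), str(cpath)]
        for _, row in classes.iterrows():
            summary[f"occupancy_{row['class']}"] = float(row["occupancy"])

    def _stage_density(opts):
        stages["density"] = {"outputs": []}
        for name in opts["selections"]:
            prof = density_profile(traj, sels[name], axis=opts["axis"],
                                   dz=opts["dz"])
            path = outdir / f"density_{name}.tsv"
            with open(path, "w") as fh:
                fh.write(f"# dimensionless density, axis={prof.axis}\n")
                fh.write(f"{prof.axis}_nm\trho_rel\tcounts\n")
                for c, dd, ct in zip(prof.centers, prof.dimensionless,
                                     prof.counts):
                    fh.write(f"{c:.8g}\t{dd:.8g}\t{ct}\n")
            stages["density"]["outputs"].append(str(path))

    def _stage_descriptors(opts):
        stages["descriptors"] = {"outputs": []}
        series = descriptor_series(traj, sels["protein"],
                                   probe=opts["probe"],
                                   n_sphere_points=opts["n_sphere_points"])
        path = outdir / "descriptors.tsv"
        series.to_csv(path, sep="\t", index=False)
        stages["descriptors"]["outputs"].append(str(path))
        summary["mean_rg_nm"] = float(series["rg_nm"].mean())
        summary["mean_sasa_nm2"] = float(series["sasa_nm2"].mean())
        summary["mean_hydrophobic_fraction"] = float(
            series["hydrophobic_fraction"].mean())

    _run("rdf", _stage_rdf)
    _run("beta", _stage_beta)
    _run("contacts", _stage_contacts)
    _run("density", _stage_density)
    _run("descriptors", _stage_descriptors)

    report = AnalysisReport(
        stages=stages, summary=summary,
        provenance={"config_hash": config.config_hash(),
                    "package_version": __version__, "seed": config.seed,
                    "n_frames_analyzed": traj.n_frames})
    (outdir / "report.json").write_text(report.to_json())
    return report
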