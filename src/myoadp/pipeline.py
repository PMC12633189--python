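"""End-to-end pipeline: configuration, stage execution, manifest.

A run configuration is a JSON document validated before any stage runs;
stages execute in dependency order, each writing TSV/JSON artifacts into
the output directory, and a manifest records stages, seeds, output hashes
and the package version. Every stochastic stage draws from an explicit
seed, so a rerun with the same configuration is bit-identical.

Analysis thresholds default to the study's printed values: 5 Å contact
cutoff, 5° dihedral bins, 3 kT pocket threshold, 0.1 Å seed tolerance,
90% contact-timeline presence filter, 1 Å/ns pull speed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, experiments, io, kinetics, mechanics, pulling, synthetic, trajectory

__all__ = ["validate_config", "run_pipeline", "demo_config", "STAGE_ORDER"]

logger = logging.getLogger("myoadp")

STAGE_ORDER = ("pulling", "trajectory", "stopped_flow", "mechanics", "summary")

DEFAULTS = {
    "pulling": {"pull_speed": 1.0, "spring_constant": 100.0, "end_position": 2.0,
                "potential_k": 1.0, "n_replicates": 8, "timestep": 0.01,
                "temperature": 310.0},
    "trajectory": {"n_frames": 60, "contact_cutoff": 5.0, "bin_width": 5.0},
    "stopped_flow": {"k_adp_true": 46.46},
    "mechanics": {"n_per_group": 4},
    "summary": {},
}


class ConfigError(ValueError):
    """Configuration rejected before any stage ran."""


def validate_config(config: dict) -> dict:
    """Schema-check a run configuration; returns a normalized copy.

    Requirements: ``output_dir`` present; integer ``seed`` (stochastic
    stages are refused without one); ``stages`` a mapping of known stage
    names to parameter blocks; any declared ``input`` path must exist.
    """
    if not isinstance(config, dict):
        raise ConfigError("configuration must be a JSON object")
    if "output_dir" not in config:
        raise ConfigError("configuration requires 'output_dir'")
    if not isinstance(config.get("seed"), int):
        raise ConfigError("an explicit integer 'seed' is required "
                          "(stochastic stages are not run unseeded)")
    stages = config.get("stages", {name: {} for name in STAGE_ORDER})
    if not isinstance(stages, dict) or not stages:
        raise ConfigError("'stages' must be a non-empty object")
    norm = {}
    for name, params in stages.items():
        if name not in STAGE_ORDER:
            raise ConfigError(f"unknown stage {name!r}; known: {STAGE_ORDER}")
        if not isinstance(params, dict):
            raise ConfigError(f"stage {name!r} parameters must be an object")
        merged = dict(DEFAULTS[name])
        merged.update(params)
        inp = merged.get("input")
        if inp is not None and not Path(inp).exists():
            raise ConfigError(f"stage {name!r}: input path {inp!r} does not exist")
        norm[name] = merged
    out = dict(config)
    out["stages"] = norm
    out.setdefault("log_level", "INFO")
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_pulling(params: dict, seed: int, outdir: Path) -> dict:
    spec = synthetic.PullingSpec(
        potential=synthetic.HarmonicPotential(k=params["potential_k"]),
        end_position=params["end_position"],
        spring_constant=params["spring_constant"],
        pull_speed=params["pull_speed"], timestep=params["timestep"],
        temperature=params["temperature"],
        n_replicates=params["n_replicates"], seed=seed)
    ens = synthetic.generate_pulling_ensemble(spec, label="demo")
    prof = pulling.jarzynski_profile(ens)
    mw = pulling.mean_work(ens)
    io.write_work_tsv(ens, outdir / "work.tsv")
    io.write_profile_tsv(prof, outdir / "profile.tsv",
                         mean_w=mw["mean_profile"], sd_w=mw["sd_profile"])
    return {"outputs": ["work.tsv", "profile.tsv"],
            "mean_work": mw["mean_final"], "jarzynski": float(prof.delta_f[-1]),
            "analytic_delta_f": ens.analytic_delta_f}


def _stage_trajectory(params: dict, seed: int, outdir: Path) -> dict:
    n = params["n_frames"]
    spec = synthetic.ToyTrajectorySpec(
        n_frames=n,
        residues=[synthetic.ResidueSpec("RA", [("A1", "C"), ("A2", "C")]),
                  synthetic.ResidueSpec("RB", [("B1", "C"), ("B2", "C")])],
        ligand_charges=(0.4, -0.6, 0.1, 0.05, 0.05),
        dihedral_states=[synthetic.DihedralState(means=(60.0, 180.0)),
                         synthetic.DihedralState(means=(-60.0, 60.0))],
        state_sequence=[(0, n // 2, 0), (n // 2, n, 1)],
        contact_schedule={(0, 1): [synthetic.ContactInterval(0, n // 3)]},
        seed=seed)
    traj = synthetic.generate_toy_trajectory(spec)
    fractions = trajectory.residue_contact_fractions(traj, cutoff=params["contact_cutoff"])
    pd.DataFrame([{"res_a": a, "res_b": b, "fraction": f}
                  for (a, b), f in fractions.items()]).to_csv(
        outdir / "contacts.tsv", sep="\t", index=False, float_format="%.6g")
    lig = traj.topology["resname"] == "LIG"
    names = traj.topology.loc[lig, "name"].tolist()
    specs = [trajectory.DihedralSpec("chi1", tuple(names[0:4])),
             trajectory.DihedralSpec("chi2", tuple(names[1:5]))]
    angles = trajectory.compute_dihedrals(traj, specs)
    dmap = trajectory.dihedral_map(angles["chi1"], angles["chi2"],
                                   bin_width=params["bin_width"],
                                   labels=("chi1", "chi2"))
    io.write_dihedral_map(dmap, outdir / "dihedral_map.tsv")
    summary = {"entropy_cal_mol_K": trajectory.conformational_entropy(dmap),
               "coverage_percent": trajectory.percent_coverage(dmap)}
    (outdir / "dihedral_summary.json").write_text(json.dumps(summary, indent=1))
    return {"outputs": ["contacts.tsv", "dihedral_map.tsv", "dihedral_summary.json"],
            **summary}


def _stage_stopped_flow(params: dict, seed: int, outdir: Path) -> dict:
    spec = synthetic.StoppedFlowSpec(k_adp_true=params["k_adp_true"], seed=seed)
    traces = synthetic.generate_stopped_flow_traces(spec)
    for tr in traces:
        io.write_trace_csv(tr, outdir / f"trace_adp{int(tr.adp_um)}.csv")
    fit = experiments.fit_binding_curve_from_traces(traces)
    result = {"k_adp_um": fit.k_adp, "se_um": fit.se,
              "k_adp_true_um": params["k_adp_true"]}
    (outdir / "kadp.json").write_text(json.dumps(result, indent=1))
    return {"outputs": ["kadp.json"], **result}


def _stage_mechanics(params: dict, seed: int, outdir: Path) -> dict:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    rows = []
    base = synthetic.ForceTraceSpec()
    for genotype, f_scale in (("WT", 1.0), ("G256E", 2.0)):
        for solution in ("5.6", "5.6ADP"):
            for rep in range(params["n_per_group"]):
                s = synthetic.ForceTraceSpec(f_ss=base.f_ss * f_scale,
                                             seed=int(rng.integers(2 ** 31)))
                if solution == "5.6ADP":
                    s = synthetic.adp_condition(s, seed=int(rng.integers(2 ** 31)))
                cond = {"pCa": solution, "genotype": genotype,
                        "atp_mm": 2.5 if solution == "5.6ADP" else 5.0,
                        "adp_mm": 2.5 if solution == "5.6ADP" else 0.0}
                trace = synthetic.generate_force_trace(s, condition=cond)
                dec = mechanics.decompose_relaxation(trace)
                rows.append({"myofibril": rep, "genotype": genotype,
                             "solution": solution,
                             "force": mechanics.steady_state_force(trace),
                             "k_act": mechanics.fit_kact(trace),
                             "k_rel_slow": dec.k_rel_slow,
                             "t_rel_slow": dec.t_rel_slow,
                             "k_rel_fast": dec.k_rel_fast})
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "mechanics.tsv", sep="\t", index=False,
                 float_format="%.6g")
    cmp = mechanics.compare_mechanics(table, "force")
    anova = {str(k): {"F": None if np.isnan(v["F"]) else float(v["F"]),
                      "p": None if np.isnan(v["PR(>F)"]) else float(v["PR(>F)"])}
             for k, v in cmp["anova"].iterrows()}
    (outdir / "anova_force.json").write_text(json.dumps(anova, indent=1))
    return {"outputs": ["mechanics.tsv", "anova_force.json"]}


def _stage_summary(params: dict, seed: int, outdir: Path,
                   results: dict | None = None) -> dict:
    (outdir / "report.json").write_text(json.dumps(results or {}, indent=1,
                                                   default=str))
    return {"outputs": ["report.json"]}


_RUNNERS = {"pulling": _stage_pulling, "trajectory": _stage_trajectory,
            "stopped_flow": _stage_stopped_flow, "mechanics": _stage_mechanics}


def run_pipeline(config: dict | str | Path) -> dict:
    """Validate, execute stages in dependency order, write the manifest.

    Returns the manifest dict. A schema violation aborts before any stage;
    a stage failure is recorded in the manifest and later stages still run.
    """
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    config = validate_config(config)
    logging.basicConfig(level=getattr(logging, config["log_level"].upper(), 20))
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config["seed"]

    manifest = {"seed": seed, "version": __version__, "stages": [],
                "outputs": {}, "failures": []}
    results = {}
    for i, name in enumerate(STAGE_ORDER):
        if name not in config["stages"]:
            continue
        params = config["stages"][name]
        stage_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2 ** 31)
        logger.info("stage %s (seed %d)", name, stage_seed)
        try:
            if name == "summary":
                info = _stage_summary(params, stage_seed, outdir, results=results)
            else:
                info = _RUNNERS[name](params, stage_seed, outdir)
            results[name] = {k: v for k, v in info.items() if k != "outputs"}
            manifest["stages"].append(name)
            for rel in info["outputs"]:
                p = outdir / rel
                manifest["outputs"][rel] = _sha256(p)
                sidecar = p.with_suffix(p.suffix + ".json")
                if sidecar.exists():
                    manifest["outputs"][sidecar.name] = _sha256(sidecar)
        except Exception as exc:  # stage failure -> partial manifest
            logger.error("stage %s failed: %s", name, exc)
            manifest["failures"].append({"stage": name, "error": str(exc)})
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def demo_config(output_dir: str | Path, seed: int = 1) -> dict:
    """The default synthetic end-to-end demonstration configuration."""
    return {"output_dir": str(output_dir), "seed": seed,
            "stages": {name: {} for name in STAGE_ORDER}}
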