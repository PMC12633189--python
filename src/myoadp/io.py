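"""Readers and writers for the package's standard file formats.

Text formats are the primary interchange: trace CSVs with JSON metadata
sidecars, work-log and descriptor TSVs, dense-matrix dihedral maps with a
small header. Trajectory I/O for standard structural formats (PDB
topologies, DCD/XTC-class frame containers) goes through mdtraj; the
lightweight frame-table text format round-trips a :class:`Trajectory`
without binary containers.

All numeric table output is written with 6 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import BindingCurve, FluorescenceTrace
from .mechanics import ForceTrace
from .pulling import ContactTimeline, FreeEnergyProfile, WorkEnsemble, resample_work
from .trajectory import DihedralMap, LieTable, Trajectory

__all__ = [
    "write_trace_csv", "read_trace_csv",
    "write_force_trace_csv", "read_force_trace_csv",
    "write_work_tsv", "read_work_tsv",
    "write_profile_tsv", "write_timeline_tsv", "write_lie_tsv",
    "write_dihedral_map", "read_dihedral_map",
    "write_frames_text", "read_frames_text",
    "trajectory_to_mdtraj", "trajectory_from_mdtraj", "load_trajectory",
    "write_dcd",
]

FLOAT_FMT = "%.6g"


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def write_trace_csv(trace: FluorescenceTrace, path: str | Path) -> None:
    """CSV (time, signal) plus a .json sidecar with condition metadata."""
    path = Path(path)
    df = pd.DataFrame({"time": trace.time, "signal": trace.signal})
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    meta = {"adp_um": trace.adp_um, "atp_um": trace.atp_um,
            "replicate": trace.replicate, "warnings": trace.warnings}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_trace_csv(path: str | Path) -> FluorescenceTrace:
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return FluorescenceTrace(time=df["time"].to_numpy(),
                             signal=df["signal"].to_numpy(),
                             adp_um=meta.get("adp_um", 0.0),
                             atp_um=meta.get("atp_um", 25.0),
                             replicate=meta.get("replicate", 0),
                             warnings=meta.get("warnings", []))


def write_force_trace_csv(trace: ForceTrace, path: str | Path) -> None:
    """CSV (time, force) plus a .json sidecar with events and condition."""
    path = Path(path)
    pd.DataFrame({"time": trace.time, "force": trace.force}).to_csv(
        path, index=False, float_format=FLOAT_FMT)
    meta = {"events": [[lab, t] for lab, t in trace.events],
            "condition": trace.condition}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_force_trace_csv(path: str | Path) -> ForceTrace:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ForceTrace(time=df["time"].to_numpy(), force=df["force"].to_numpy(),
                      events=[(lab, t) for lab, t in meta["events"]],
                      condition=meta.get("condition", {}))


# ---------------------------------------------------------------------------
# work ensembles / profiles / timelines
# ---------------------------------------------------------------------------

def write_work_tsv(ensemble: WorkEnsemble, path: str | Path) -> None:
    """Long-format TSV: replicate, lambda, W."""
    rows = []
    for i in range(ensemble.n_replicates):
        for lam, w in zip(ensemble.lam, ensemble.work[i]):
            rows.append((i, lam, w))
    df = pd.DataFrame(rows, columns=["replicate", "lambda", "W"])
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_work_tsv(path: str | Path, temperature: float,
                  grid_step: float = 0.1, label: str = "") -> WorkEnsemble:
    """Rebuild a WorkEnsemble from a (replicate, lambda, W) TSV, resampling
    onto a common grid."""
    df = pd.read_csv(path, sep="\t")
    logs = [(g["lambda"].to_numpy(), g["W"].to_numpy())
            for _, g in df.groupby("replicate")]
    return resample_work(logs, temperature=temperature, grid_step=grid_step,
                         label=label)


def write_profile_tsv(profile: FreeEnergyProfile, path: str | Path,
                      mean_w: np.ndarray | None = None,
                      sd_w: np.ndarray | None = None) -> None:
    data = {"lambda": profile.lam, "delta_F": profile.delta_f}
    if mean_w is not None:
        data["mean_W"] = mean_w
    if sd_w is not None:
        data["sd_W"] = sd_w
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_timeline_tsv(timeline: ContactTimeline, path: str | Path) -> None:
    rows = []
    for k, cid in enumerate(timeline.contacts):
        for t, p in zip(timeline.times, timeline.probability[k]):
            rows.append((str(cid), t, p))
    pd.DataFrame(rows, columns=["contact", "t", "probability"]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_lie_tsv(table: LieTable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# dihedral maps
# ---------------------------------------------------------------------------

def write_dihedral_map(dmap: DihedralMap, path: str | Path) -> None:
    """Dense count matrix with a two-line header (axis labels, bin width)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# labels\t{dmap.labels[0]}\t{dmap.labels[1]}\n")
        fh.write(f"# bin_width\t{dmap.bin_width}\n")
        np.savetxt(fh, dmap.counts, fmt="%d", delimiter="\t")


def read_dihedral_map(path: str | Path) -> DihedralMap:
    path = Path(path)
    with open(path) as fh:
        labels = fh.readline().strip().split("\t")[1:]
        bin_width = float(fh.readline().strip().split("\t")[1])
        counts = np.loadtxt(fh, delimiter="\t", dtype=int)
    return DihedralMap(labels=tuple(labels), bin_width=bin_width, counts=counts)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def write_frames_text(traj: Trajectory, frames_path: str | Path,
                      topology_path: str | Path) -> None:
    """Frame table (frame, atom, x, y, z in Å) + topology TSV."""
    n_f, n_a, _ = traj.coords.shape
    frame_idx = np.repeat(np.arange(n_f), n_a)
    atom_idx = np.tile(np.arange(n_a), n_f)
    flat = traj.coords.reshape(-1, 3)
    pd.DataFrame({"frame": frame_idx, "atom": atom_idx,
                  "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2]}
                 ).to_csv(frames_path, sep="\t", index=False, float_format="%.8g")
    traj.topology.to_csv(topology_path, sep="\t", index=False)


def read_frames_text(frames_path: str | Path, topology_path: str | Path,
                     frame_interval_ps: float = 10.0) -> Trajectory:
    top = pd.read_csv(topology_path, sep="\t")
    df = pd.read_csv(frames_path, sep="\t")
    n_f = int(df["frame"].max()) + 1
    n_a = len(top)
    coords = df[["x", "y", "z"]].to_numpy().reshape(n_f, n_a, 3)
    return Trajectory(coords=coords, topology=top,
                      frame_interval_ps=frame_interval_ps)


_DEFAULT_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                 "P": 30.974, "S": 32.06, "MG": 24.305}


def trajectory_to_mdtraj(traj: Trajectory):
    """Convert to an mdtraj.Trajectory (nm) for standard-format output."""
    import mdtraj as md
    from mdtraj.core import element as elem

    top = md.Topology()
    chain = top.add_chain()
    residues = {}
    for _, row in traj.topology.iterrows():
        rid = int(row["resid"])
        if rid not in residues:
            residues[rid] = top.add_residue(str(row["resname"]), chain)
        try:
            e = elem.get_by_symbol(str(row["element"]).capitalize())
        except KeyError:
            e = elem.virtual
        top.add_atom(str(row["name"]), e, residues[rid])
    return md.Trajectory(xyz=traj.coords / 10.0, topology=top)


def trajectory_from_mdtraj(mdt, charges=None, sigma=None, epsilon=None,
                           frame_interval_ps: float = 10.0) -> Trajectory:
    """Convert an mdtraj.Trajectory (nm) into the package container (Å).

    Charges/LJ parameters are not carried by structural formats; pass them
    explicitly when interaction energies are needed.
    """
    n = mdt.n_atoms
    rows = []
    for atom in mdt.topology.atoms:
        sym = atom.element.symbol.upper() if atom.element is not None else "C"
        rows.append({"name": atom.name, "element": sym if sym != "MG" else "Mg",
                     "resid": atom.residue.index, "resname": atom.residue.name,
                     "mass": _DEFAULT_MASS.get(sym, 12.0)})
    top = pd.DataFrame(rows)
    top["element"] = top["element"].replace({"Mg": "MG"})
    top["charge"] = np.asarray(charges, dtype=float) if charges is not None else np.nan
    top["sigma"] = np.asarray(sigma, dtype=float) if sigma is not None else np.nan
    top["epsilon"] = np.asarray(epsilon, dtype=float) if epsilon is not None else np.nan
    return Trajectory(coords=np.asarray(mdt.xyz, dtype=float) * 10.0,
                      topology=top, frame_interval_ps=frame_interval_ps)


def load_trajectory(topology_pdb: str | Path,
                    frames: str | Path | None = None,
                    frame_interval_ps: float = 10.0) -> Trajectory:
    """Load a PDB topology, optionally with a DCD/XTC-class frame file."""
    import mdtraj as md

    if frames is None:
        mdt = md.load(str(topology_pdb))
    else:
        mdt = md.load(str(frames), top=str(topology_pdb))
    return trajectory_from_mdtraj(mdt, frame_interval_ps=frame_interval_ps)


def write_dcd(traj: Trajectory, dcd_path: str | Path,
              pdb_path: str | Path | None = None) -> None:
    """Write frames to a DCD container (plus optional PDB topology)."""
    mdt = trajectory_to_mdtraj(traj)
    mdt.save_dcd(str(dcd_path))
    if pdb_path is not None:
        mdt[0].save_pdb(str(pdb_path))
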