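"""Descriptor computations on molecular trajectories.

The central container is :class:`Trajectory`: an ``(n_frames, n_atoms, 3)``
coordinate array in Å plus a per-atom topology table (pandas DataFrame) that
carries residue assignment, element, mass and — when available — partial
charges and Lennard-Jones parameters. This is deliberately lighter than an
engine topology: every descriptor here (RMSD/RMSF, heavy-atom contacts,
nucleotide dihedral maps with entropy and coverage, linear interaction
energies, center-of-mass reaction coordinates, occupancy grids) needs only
these annotations, and the container converts to/from mdtraj objects for
standard-format I/O (see :mod:`myoadp.io`).

Conventions
-----------
* Torsion angles are signed, in degrees, on (−180, 180].
* Contacts: two residues are in contact in a frame iff the minimum distance
  between any pair of their heavy atoms is ≤ the cutoff (default 5 Å).
* Conformational entropy of a 2-D dihedral histogram is the Gibbs entropy
  S = −R Σ pᵢ ln pᵢ in cal mol⁻¹ K⁻¹.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import COULOMB_CONSTANT, R_CAL, kT

__all__ = [
    "Trajectory",
    "DihedralSpec",
    "DihedralMap",
    "LieTable",
    "OccupancyGrid",
    "kabsch_rotation",
    "superpose",
    "rmsd_to_reference",
    "rmsf",
    "residue_contact_fractions",
    "residue_contact_series",
    "salt_bridge_persistence",
    "compute_dihedrals",
    "dihedral_map",
    "conformational_entropy",
    "percent_coverage",
    "linear_interaction_energy",
    "build_lie_table",
    "select_pocket_residues",
    "com_distance_series",
    "modal_distance",
    "select_seed_frames",
    "occupancy_grid",
    "group_vector_angle",
]

TOPOLOGY_COLUMNS = ("name", "element", "resid", "resname", "mass", "charge", "sigma", "epsilon")

# Selection: None (all atoms), an index/boolean array, or a predicate on the
# topology DataFrame returning a boolean mask.
Selection = None | Sequence[int] | np.ndarray | Callable[[pd.DataFrame], "np.ndarray"]


@dataclass
class Trajectory:
    """Ordered coordinate frames plus a per-atom annotation table.

    Parameters
    ----------
    coords
        Array of shape (n_frames, n_atoms, 3), Å.
    topology
        DataFrame with one row per atom; required columns ``name``,
        ``element``, ``resid``, ``resname``, ``mass``; optional ``charge``,
        ``sigma`` (Å), ``epsilon`` (kcal/mol).
    frame_interval_ps
        Time between saved frames, ps.
    """

    coords: np.ndarray
    topology: pd.DataFrame
    frame_interval_ps: float = 10.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.topology) != self.coords.shape[1]:
            raise ValueError(
                f"topology has {len(self.topology)} atoms but coords have "
                f"{self.coords.shape[1]}"
            )
        for col in ("name", "element", "resid", "resname", "mass"):
            if col not in self.topology.columns:
                raise ValueError(f"topology missing required column {col!r}")
        self.topology = self.topology.reset_index(drop=True)

    # -- basic views -------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def heavy_mask(self) -> np.ndarray:
        """Boolean mask of heavy (non-hydrogen) atoms."""
        return (self.topology["element"].to_numpy() != "H")

    def atom_indices(self, selection: Selection) -> np.ndarray:
        """Resolve a selection to sorted atom indices."""
        if selection is None:
            return np.arange(self.n_atoms)
        if callable(selection):
            mask = np.asarray(selection(self.topology))
            if mask.dtype == bool:
                return np.flatnonzero(mask)
            return np.sort(mask.astype(int))
        arr = np.asarray(selection)
        if arr.dtype == bool:
            if arr.size != self.n_atoms:
                raise ValueError("boolean selection length mismatch")
            return np.flatnonzero(arr)
        return np.sort(arr.astype(int))

    def residue_atoms(self, resid: int, heavy_only: bool = False) -> np.ndarray:
        mask = self.topology["resid"].to_numpy() == resid
        if heavy_only:
            mask &= self.heavy_mask
        return np.flatnonzero(mask)

    def residue_ids(self) -> np.ndarray:
        return np.unique(self.topology["resid"].to_numpy())


# ---------------------------------------------------------------------------
# superposition / RMSD / RMSF
# ---------------------------------------------------------------------------

def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal (least-squares, unweighted) rotation mapping centered ``mobile``
    onto centered ``reference``; the proper-rotation branch of the SVD solution.
    """
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    return vt.T @ correction @ u.T


def superpose(mobile: np.ndarray, reference: np.ndarray,
              fit_idx: np.ndarray | None = None) -> np.ndarray:
    """Rigidly superpose one frame onto a reference.

    The transform (translation + Kabsch rotation) is computed on ``fit_idx``
    atoms (all atoms if None) and applied to the whole frame.
    """
    if fit_idx is None:
        fit_idx = np.arange(mobile.shape[0])
    mob_fit = mobile[fit_idx]
    ref_fit = reference[fit_idx]
    mob_center = mob_fit.mean(axis=0)
    ref_center = ref_fit.mean(axis=0)
    rot = kabsch_rotation(mob_fit - mob_center, ref_fit - ref_center)
    return (mobile - mob_center) @ rot.T + ref_center


def rmsd_to_reference(traj: Trajectory, reference: np.ndarray,
                      selection: Selection = None) -> np.ndarray:
    """Per-frame RMSD (Å) to a reference frame after optimal superposition.

    Each frame is superposed on the reference (unweighted Kabsch on the
    selection) before the RMSD over the selected atoms is computed — the
    standard convention for RMSD relative to a minimized starting structure.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (traj.n_atoms, 3):
        raise ValueError("reference frame must match trajectory atom count")
    idx = traj.atom_indices(selection)
    if idx.size == 0:
        raise ValueError("empty atom selection")
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        fitted = superpose(traj.coords[f], reference, fit_idx=idx)
        d = fitted[idx] - reference[idx]
        out[f] = np.sqrt((d * d).sum() / idx.size)
    return out


def rmsf(traj: Trajectory, selection: Selection = None,
         align_selection: Selection = None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation (Å) about the average structure.

    Two-pass procedure: frames are first aligned to a provisional average,
    the average is recomputed from the aligned frames, and fluctuations are
    measured against that refined mean — i.e. RMSF after aligning the
    trajectory to the average structure.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    idx = traj.atom_indices(selection)
    fit_idx = traj.atom_indices(align_selection)
    # provisional mean: align everything onto frame 0 first
    aligned = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        aligned[f] = superpose(traj.coords[f], traj.coords[0], fit_idx=fit_idx)
    mean = aligned.mean(axis=0)
    for f in range(traj.n_frames):
        aligned[f] = superpose(traj.coords[f], mean, fit_idx=fit_idx)
    mean = aligned.mean(axis=0)
    d = aligned[:, idx, :] - mean[idx]
    return np.sqrt((d * d).sum(axis=2).mean(axis=0))


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((diff * diff).sum(axis=2)).min())


def residue_contact_series(traj: Trajectory, pairs: Sequence[tuple[int, int]],
                           cutoff: float = 5.0) -> np.ndarray:
    """Boolean (n_pairs, n_frames) array: heavy-atom contact per frame."""
    atom_sets = {}
    for i, j in pairs:
        for r in (i, j):
            if r not in atom_sets:
                atom_sets[r] = traj.residue_atoms(r, heavy_only=True)
    out = np.zeros((len(pairs), traj.n_frames), dtype=bool)
    for p, (i, j) in enumerate(pairs):
        ai, aj = atom_sets[i], atom_sets[j]
        if ai.size == 0 or aj.size == 0:
            continue
        for f in range(traj.n_frames):
            out[p, f] = _min_dist(traj.coords[f, ai], traj.coords[f, aj]) <= cutoff
    return out


def residue_contact_fractions(traj: Trajectory, cutoff: float = 5.0,
                              pairs: Sequence[tuple[int, int]] | None = None,
                              ) -> dict[tuple[int, int], float]:
    """Fraction of frames each residue pair spends in heavy-atom contact.

    A pair is contacting in a frame iff at least one pair of heavy atoms
    between the two residues is within ``cutoff`` Å. When ``pairs`` is None
    every unordered residue pair is evaluated (intended for toy systems).
    """
    if not traj.heavy_mask.any():
        raise ValueError("trajectory has no heavy atoms")
    if pairs is None:
        resids = traj.residue_ids()
        pairs = [(int(a), int(b)) for k, a in enumerate(resids) for b in resids[k + 1:]]
    series = residue_contact_series(traj, pairs, cutoff=cutoff)
    return {tuple(p): float(series[k].mean()) for k, p in enumerate(pairs)}


# side-chain charged-group atoms for standard residues (N/O heavy atoms)
_CHARGED_GROUP_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}


def _charged_group(traj: Trajectory, resid: int) -> np.ndarray:
    rows = traj.topology[traj.topology["resid"] == resid]
    if rows.empty:
        raise ValueError(f"residue {resid} not in topology")
    resname = rows["resname"].iloc[0]
    names = _CHARGED_GROUP_ATOMS.get(str(resname).upper())
    if names is not None:
        idx = rows.index[rows["name"].isin(names)].to_numpy()
        if idx.size:
            return idx
    # fall back to charge annotation: N/O heavy atoms carrying partial charge
    if "charge" in rows.columns:
        mask = rows["element"].isin(["N", "O"]) & (rows["charge"].abs() >= 0.3)
        idx = rows.index[mask.fillna(False)].to_numpy()
        if idx.size:
            return idx
    raise ValueError(f"residue {resid} ({resname}) has no charged side-chain group")


def salt_bridge_persistence(traj: Trajectory, res_a: int, res_b: int,
                            cutoff: float = 4.0) -> float:
    """Fraction of frames with a salt bridge between two residues.

    Criterion: minimum distance between side-chain charged-group N/O atoms
    ≤ ``cutoff`` (4.0 Å default, the standard structural-biology threshold).
    """
    ga = _charged_group(traj, res_a)
    gb = _charged_group(traj, res_b)
    count = 0
    for f in range(traj.n_frames):
        if _min_dist(traj.coords[f, ga], traj.coords[f, gb]) <= cutoff:
            count += 1
    return count / traj.n_frames


# ---------------------------------------------------------------------------
# dihedrals, maps, entropy, coverage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DihedralSpec:
    """A named torsion defined by four atom names (e.g. the six angles
    θ₁…θ₆ describing bound-ADP conformation, θ₁ = O1B-PB-O3A-PA)."""

    label: str
    atoms: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if len(set(self.atoms)) != 4:
            raise ValueError("dihedral requires four distinct atom names")


#: The six ADP internal torsions: phosphate tail (θ1–θ4), ribose linkage (θ5)
#: and the glycosidic angle (θ6).
ADP_DIHEDRALS = (
    DihedralSpec("theta1", ("O1B", "PB", "O3A", "PA")),
    DihedralSpec("theta2", ("PB", "O3A", "PA", "O5'")),
    DihedralSpec("theta3", ("O3A", "PA", "O5'", "C5'")),
    DihedralSpec("theta4", ("PA", "O5'", "C5'", "C4'")),
    DihedralSpec("theta5", ("O5'", "C5'", "C4'", "O4'")),
    DihedralSpec("theta6", ("O4'", "C1'", "N9", "C8")),
)


def dihedral_from_positions(p: np.ndarray) -> float:
    """Signed torsion (degrees, (−180, 180]) from four positions (4, 3).

    Returns NaN when a bonded triplet is collinear (torsion undefined).
    """
    b1 = p[1] - p[0]
    b2 = p[2] - p[1]
    b3 = p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        return float("nan")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(n1 @ n2)
    y = float(m @ n2)
    return float(np.degrees(np.arctan2(y, x)))


def compute_dihedrals(traj: Trajectory, specs: Iterable[DihedralSpec],
                      within_resid: int | None = None) -> pd.DataFrame:
    """Per-frame torsion series for each spec, degrees on (−180, 180].

    Atom names are resolved in the topology (optionally restricted to one
    residue); frames with a collinear triplet are flagged NaN.
    """
    top = traj.topology
    if within_resid is not None:
        top = top[top["resid"] == within_resid]
    series = {}
    for spec in specs:
        idx = []
        for name in spec.atoms:
            hits = top.index[top["name"] == name].to_numpy()
            if hits.size == 0:
                raise ValueError(f"atom {name!r} of dihedral {spec.label} not in topology")
            idx.append(int(hits[0]))
        vals = np.array([dihedral_from_positions(traj.coords[f, idx])
                         for f in range(traj.n_frames)])
        series[spec.label] = vals
    return pd.DataFrame(series)


@dataclass
class DihedralMap:
    """2-D torsion histogram (Ramachandran-style) over [−180, 180)².

    ``counts`` is the raw (nx, ny) integer grid, ``probability`` its
    normalization; ``bin_width`` must divide 360 evenly (default 5° gives
    the 72×72 grid used for nucleotide conformation maps).
    """

    labels: tuple[str, str]
    bin_width: float
    counts: np.ndarray
    probability: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = 360.0 / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("bin width must divide 360 evenly")
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("negative histogram counts")
        total = self.counts.sum()
        if total == 0:
            raise ValueError("empty dihedral map")
        self.probability = self.counts / total

    @property
    def n_bins(self) -> int:
        return self.counts.size


def dihedral_map(x: np.ndarray, y: np.ndarray, bin_width: float = 5.0,
                 labels: tuple[str, str] = ("x", "y")) -> DihedralMap:
    """Build the joint 2-D histogram of two equal-length angle series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty angle series")
    if x.shape != y.shape:
        raise ValueError("angle series must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size == 0:
        raise ValueError("no defined angles in series")
    # fold the closed +180 endpoint into the [-180, 180) bin convention
    x = np.where(x == 180.0, -180.0, x)
    y = np.where(y == 180.0, -180.0, y)
    n = int(round(360.0 / bin_width))
    edges = np.linspace(-180.0, 180.0, n + 1)
    counts, _, _ = np.histogram2d(x, y, bins=(edges, edges))
    return DihedralMap(labels=labels, bin_width=bin_width, counts=counts.astype(int))


def conformational_entropy(dmap: DihedralMap) -> float:
    """Gibbs entropy S = −R Σ pᵢ ln pᵢ of the map, cal mol⁻¹ K⁻¹ (0·ln 0 ≡ 0).

    Lower values indicate a more restricted ligand pose; the maximum is
    R ln N_bins for a uniform map.
    """
    p = dmap.probability[dmap.probability > 0]
    return float(-R_CAL * (p * np.log(p)).sum())


def percent_coverage(dmap: DihedralMap) -> float:
    """Percentage of map bins visited at least once."""
    return 100.0 * float((dmap.counts >= 1).sum()) / dmap.n_bins


# ---------------------------------------------------------------------------
# interaction energies
# ---------------------------------------------------------------------------

def linear_interaction_energy(traj: Trajectory, residue_sel: Selection,
                              ligand_sel: Selection,
                              cutoff: float | None = None,
                              ) -> dict[str, float]:
    """Mean residue–ligand interaction energy over the trajectory, kcal/mol.

    Per frame the pairwise vacuum Coulomb term (332.0636 qᵢqⱼ/r) and the
    Lennard-Jones 12-6 term (Lorentz–Berthelot combining) are summed over all
    residue-atom × ligand-atom pairs, then averaged over frames. Returns
    ``electrostatic``, ``vdw`` and ``combined`` (their sum). ``cutoff``
    optionally discards pairs beyond that distance (per frame); the default
    applies no cutoff, appropriate for small toy systems.
    """
    ri = traj.atom_indices(residue_sel)
    li = traj.atom_indices(ligand_sel)
    if ri.size == 0 or li.size == 0:
        raise ValueError("empty residue or ligand selection")
    top = traj.topology
    if "charge" not in top.columns or top["charge"].isna().any():
        missing = top.loc[top["charge"].isna(), "name"].tolist() if "charge" in top.columns else "all"
        raise ValueError(f"partial charges missing for atoms: {missing}")
    q = top["charge"].to_numpy(dtype=float)
    sigma = top["sigma"].to_numpy(dtype=float) if "sigma" in top.columns else np.zeros(traj.n_atoms)
    eps = top["epsilon"].to_numpy(dtype=float) if "epsilon" in top.columns else np.zeros(traj.n_atoms)
    if np.isnan(sigma).any() or np.isnan(eps).any():
        bad = top.loc[np.isnan(sigma) | np.isnan(eps), "name"].tolist()
        raise ValueError(f"Lennard-Jones parameters missing for atoms: {bad}")

    qq = COULOMB_CONSTANT * np.outer(q[ri], q[li])
    sig_ij = 0.5 * (sigma[ri][:, None] + sigma[li][None, :])
    eps_ij = np.sqrt(np.outer(eps[ri], eps[li]))

    elec_sum = 0.0
    vdw_sum = 0.0
    for f in range(traj.n_frames):
        diff = traj.coords[f, ri][:, None, :] - traj.coords[f, li][None, :, :]
        r = np.sqrt((diff * diff).sum(axis=2))
        mask = r > 0
        if cutoff is not None:
            mask &= r <= cutoff
        with np.errstate(divide="ignore", invalid="ignore"):
            elec = np.where(mask, qq / r, 0.0)
            sr6 = np.where(mask, (sig_ij / np.where(mask, r, 1.0)) ** 6, 0.0)
            vdw = 4.0 * eps_ij * (sr6 * sr6 - sr6)
        elec_sum += elec.sum()
        vdw_sum += vdw[mask].sum() if cutoff is not None else vdw.sum()
    n = traj.n_frames
    elec_mean = elec_sum / n
    vdw_mean = vdw_sum / n
    return {"electrostatic": elec_mean, "vdw": vdw_mean,
            "combined": elec_mean + vdw_mean}


@dataclass
class LieTable:
    """Per-residue mean interaction energies with one or more ligand groups.

    ``table`` columns: resid, ligand, electrostatic, vdw, combined
    (combined = electrostatic + vdw by construction).
    """

    table: pd.DataFrame
    temperature: float = 310.0

    def __post_init__(self) -> None:
        required = {"resid", "ligand", "electrostatic", "vdw", "combined"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"LIE table requires columns {sorted(required)}")
        resid = self.table["combined"] - (self.table["electrostatic"] + self.table["vdw"])
        if not np.allclose(resid, 0.0, atol=1e-9):
            raise ValueError("combined energy must equal electrostatic + vdw")


def build_lie_table(traj: Trajectory, ligand_groups: Mapping[str, Selection],
                    residues: Sequence[int] | None = None,
                    cutoff: float | None = None,
                    temperature: float = 310.0) -> LieTable:
    """LIE table of every residue against each named ligand group."""
    if residues is None:
        ligand_atoms = set()
        for sel in ligand_groups.values():
            ligand_atoms.update(traj.atom_indices(sel).tolist())
        residues = [int(r) for r in traj.residue_ids()
                    if not set(traj.residue_atoms(int(r))).issubset(ligand_atoms)]
    rows = []
    for resid in residues:
        ridx = traj.residue_atoms(int(resid))
        for ligand, sel in ligand_groups.items():
            e = linear_interaction_energy(traj, ridx, sel, cutoff=cutoff)
            rows.append({"resid": int(resid), "ligand": ligand, **{
                "electrostatic": e["electrostatic"], "vdw": e["vdw"],
                "combined": e["combined"]}})
    return LieTable(table=pd.DataFrame(rows), temperature=temperature)


def select_pocket_residues(table: LieTable, threshold_kT: float = 3.0,
                           temperature: float | None = None) -> set[int]:
    """Residues interacting with any ligand group at ≥ ``threshold_kT`` · kT.

    A residue qualifies when |combined mean energy| with at least one ligand
    group reaches the threshold (3 kT ≈ 1.85 kcal/mol at 310 K) — the
    criterion used to define nucleotide-binding-pocket membership.
    """
    if table.table.empty:
        return set()
    temp = table.temperature if temperature is None else temperature
    thr = threshold_kT * kT(temp)
    t = table.table
    hits = t.loc[t["combined"].abs() >= thr, "resid"]
    return set(int(r) for r in hits.unique())


# ---------------------------------------------------------------------------
# reaction coordinate, modal distance, seed frames
# ---------------------------------------------------------------------------

def _com_series(traj: Trajectory, idx: np.ndarray) -> np.ndarray:
    m = traj.topology["mass"].to_numpy(dtype=float)[idx]
    if m.sum() <= 0:
        raise ValueError("zero total mass in group")
    return (traj.coords[:, idx, :] * m[None, :, None]).sum(axis=1) / m.sum()


def com_distance_series(traj: Trajectory, group_a: Selection,
                        group_b: Selection) -> np.ndarray:
    """Per-frame distance (Å) between mass-weighted centers of two groups."""
    ia = traj.atom_indices(group_a)
    ib = traj.atom_indices(group_b)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("empty group selection")
    diff = _com_series(traj, ia) - _com_series(traj, ib)
    return np.sqrt((diff * diff).sum(axis=1))


def modal_distance(series: np.ndarray, bin_width: float = 0.1) -> float:
    """Center of the most-populated distance bin; ties resolve to the
    smaller distance."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty distance series")
    lo = np.floor(series.min() / bin_width) * bin_width
    hi = np.ceil(series.max() / bin_width) * bin_width
    n = max(int(round((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n + 1)
    counts, _ = np.histogram(series, bins=edges)
    k = int(np.argmax(counts))  # argmax returns the first (smallest) maximum
    return float(edges[k] + bin_width / 2.0)


def select_seed_frames(series_by_replicate: Mapping[object, np.ndarray],
                       target: float, tolerance: float = 0.1,
                       per_replicate: int = 20) -> dict[object, np.ndarray]:
    """Pick up to ``per_replicate`` frames per replicate whose reaction-
    coordinate value lies within ``tolerance`` of ``target``.

    Qualifying frames are thinned evenly by frame index to avoid temporal
    clustering. Replicates without qualifying frames contribute none and
    raise a warning.
    """
    out: dict[object, np.ndarray] = {}
    for rep, series in series_by_replicate.items():
        series = np.asarray(series, dtype=float)
        qual = np.flatnonzero(np.abs(series - target) <= tolerance)
        if qual.size == 0:
            warnings.warn(f"replicate {rep!r}: no frames within {tolerance} Å of "
                          f"{target} Å", stacklevel=2)
            out[rep] = qual
            continue
        if qual.size <= per_replicate:
            out[rep] = qual
        else:
            pick = np.unique(np.round(np.linspace(0, qual.size - 1, per_replicate)).astype(int))
            out[rep] = qual[pick]
    return out


# ---------------------------------------------------------------------------
# occupancy grid & group-vector angle
# ---------------------------------------------------------------------------

@dataclass
class OccupancyGrid:
    """Voxelized visit counts for a ligand atom group on an aligned trajectory."""

    origin: np.ndarray
    spacing: float
    counts: np.ndarray

    @property
    def iso_level(self) -> float:
        """Display threshold: mean + 2·SD of the nonzero-voxel counts."""
        nz = self.counts[self.counts > 0]
        if nz.size == 0:
            return 0.0
        return float(nz.mean() + 2.0 * nz.std())


def occupancy_grid(traj: Trajectory, group: Selection,
                   spacing: float = 0.5) -> OccupancyGrid:
    """Count visits of group atoms to voxels of edge ``spacing`` Å.

    The trajectory is assumed already aligned on a reference selection, so
    voxel coordinates are meaningful across frames.
    """
    idx = traj.atom_indices(group)
    if idx.size == 0:
        raise ValueError("empty atom group")
    pts = traj.coords[:, idx, :].reshape(-1, 3)
    origin = np.floor(pts.min(axis=0) / spacing) * spacing
    ijk = np.floor((pts - origin) / spacing).astype(int)
    shape = ijk.max(axis=0) + 1
    counts = np.zeros(shape, dtype=int)
    np.add.at(counts, tuple(ijk.T), 1)
    return OccupancyGrid(origin=origin, spacing=spacing, counts=counts)


def group_vector_angle(traj: Trajectory,
                       pair_a: tuple[Selection, Selection],
                       pair_b: tuple[Selection, Selection]) -> np.ndarray:
    """Per-frame angle (degrees) between two COM-difference vectors.

    Each pair defines a vector from the mass-weighted center of its first
    group to that of its second (e.g. a lever-arm axis vs a filament axis).
    Frames with a zero-length vector are flagged NaN.
    """
    vecs = []
    for a, b in (pair_a, pair_b):
        ia, ib = traj.atom_indices(a), traj.atom_indices(b)
        if ia.size == 0 or ib.size == 0:
            raise ValueError("empty group in vector definition")
        vecs.append(_com_series(traj, ib) - _com_series(traj, ia))
    v1, v2 = vecs
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    ok = (n1 > 1e-12) & (n2 > 1e-12)
    cosang = np.full(traj.n_frames, np.nan)
    cosang[ok] = (v1[ok] * v2[ok]).sum(axis=1) / (n1[ok] * n2[ok])
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
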