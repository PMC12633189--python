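"""Synthetic-data generators with known ground truth.

Every input class consumed by the analysis modules can be generated here
with prescribed parameters, so each estimator is testable against an exact
answer:

* :func:`generate_pulling_ensemble` — ensembles of overdamped-Langevin
  steered-pulling work curves on a 1-D potential with an analytic
  free-energy difference (validates the Jarzynski machinery). This is a
  deliberately minimal surrogate for an all-atom steered simulation: a
  single coordinate q in a potential U(q), dragged by a stiff harmonic
  guide moving at constant speed, with the external work accumulated as
  W += κ_s (λ − q) · v · Δt.
* :func:`generate_stopped_flow_traces` — double-exponential fluorescence
  decays whose fast-phase rate obeys the competitive-inhibition law
  k_f = k₀ / (1 + [ADP]/K_ADP).
* :func:`generate_force_trace` — piecewise myofibril force traces
  (exponential rise → plateau → linear slow relaxation → exponential fast
  relaxation) with Gaussian noise.
* :func:`generate_toy_trajectory` — bead "pocket + ligand" trajectories
  realizing prescribed residue-contact schedules and ligand torsion-state
  schedules, with partial charges and LJ parameters for interaction-energy
  testing.

All generators are deterministic under their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.integrate import quad

from .constants import kT as thermal_energy
from .kinetics import FluorescenceTrace
from .mechanics import ForceTrace
from .pulling import WorkEnsemble
from .trajectory import Trajectory

__all__ = [
    "ZeroPotential",
    "HarmonicPotential",
    "DoubleWellPotential",
    "TabulatedPotential",
    "PullingSpec",
    "IntegratorInstabilityError",
    "generate_pulling_ensemble",
    "guide_free_energy_difference",
    "StoppedFlowSpec",
    "wt_stopped_flow_spec",
    "g256e_stopped_flow_spec",
    "generate_stopped_flow_traces",
    "ForceTraceSpec",
    "adp_condition",
    "generate_force_trace",
    "ResidueSpec",
    "DihedralState",
    "ContactInterval",
    "ToyTrajectorySpec",
    "generate_toy_trajectory",
]


# ---------------------------------------------------------------------------
# 1-D potentials
# ---------------------------------------------------------------------------

class ZeroPotential:
    """Flat energy surface: ΔF = 0 for any pull."""

    pot_id = 0
    params = (0.0, 0.0)

    def energy(self, q):
        return np.zeros_like(np.asarray(q, dtype=float))

    def max_curvature(self) -> float:
        return 0.0


@dataclass(frozen=True)
class HarmonicPotential:
    """U(q) = ½ k (q − center)², kcal/mol with k in kcal/mol/Å²."""

    k: float
    center: float = 0.0
    pot_id = 1

    @property
    def params(self):
        return (self.k, self.center)

    def energy(self, q):
        q = np.asarray(q, dtype=float)
        return 0.5 * self.k * (q - self.center) ** 2

    def max_curvature(self) -> float:
        return self.k


@dataclass(frozen=True)
class DoubleWellPotential:
    """U(q) = a ((q/b)² − 1)²: minima at ±b, barrier height a at q = 0."""

    barrier: float
    half_separation: float
    pot_id = 2

    @property
    def params(self):
        return (self.barrier, self.half_separation)

    def energy(self, q):
        q = np.asarray(q, dtype=float)
        return self.barrier * ((q / self.half_separation) ** 2 - 1.0) ** 2

    def max_curvature(self) -> float:
        # |U''| is largest at the well bottoms: 8a/b²
        return 8.0 * self.barrier / self.half_separation ** 2


@dataclass
class TabulatedPotential:
    """U(q) from a table, linearly interpolated; force from the gradient."""

    q: np.ndarray
    u: np.ndarray
    pot_id = 3

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("tabulated q must be strictly increasing")
        self.force_table = -np.gradient(self.u, self.q)

    @property
    def params(self):
        return (0.0, 0.0)

    def energy(self, q):
        return np.interp(q, self.q, self.u)

    def max_curvature(self) -> float:
        d2 = np.gradient(np.gradient(self.u, self.q), self.q)
        return float(np.abs(d2).max())


@njit(cache=True)
def _pot_force(q, pot_id, p0, p1, tab_q, tab_f):
    if pot_id == 0:
        return 0.0
    if pot_id == 1:
        return -p0 * (q - p1)
    if pot_id == 2:
        # U = a((q/b)^2 - 1)^2
        return -4.0 * p0 * q * ((q / p1) ** 2 - 1.0) / p1 ** 2
    # tabulated: linear interpolation, clamped at the table edges
    if q <= tab_q[0]:
        return tab_f[0]
    if q >= tab_q[-1]:
        return tab_f[-1]
    j = np.searchsorted(tab_q, q) - 1
    w = (q - tab_q[j]) / (tab_q[j + 1] - tab_q[j])
    return tab_f[j] * (1.0 - w) + tab_f[j + 1] * w


@njit(cache=True)
def _pull_replicate(seed, n_equil, n_steps, dt, lam0, v_ps, ks, zeta, kT,
                    pot_id, p0, p1, tab_q, tab_f, save_stride, n_save):
    """Overdamped Euler–Maruyama pull of a single replicate.

    Returns the accumulated guide work and the particle position at each
    saved frame (frame 0 is the pull start, W = 0).
    """
    np.random.seed(seed)
    sig = np.sqrt(2.0 * kT * dt / zeta)
    q = lam0
    for _ in range(n_equil):
        f = _pot_force(q, pot_id, p0, p1, tab_q, tab_f) + ks * (lam0 - q)
        q += f * dt / zeta + sig * np.random.normal()
    w_out = np.empty(n_save)
    q_out = np.empty(n_save)
    w_out[0] = 0.0
    q_out[0] = q
    w = 0.0
    isave = 1
    for step in range(1, n_steps + 1):
        lam = lam0 + v_ps * dt * (step - 1)
        f = _pot_force(q, pot_id, p0, p1, tab_q, tab_f) + ks * (lam - q)
        w += ks * (lam - q) * v_ps * dt
        q += f * dt / zeta + sig * np.random.normal()
        if step % save_stride == 0 and isave < n_save:
            w_out[isave] = w
            q_out[isave] = q
            isave += 1
    return w_out, q_out


class IntegratorInstabilityError(ValueError):
    """Timestep too large for the requested friction/stiffness."""


@dataclass
class PullingSpec:
    """Conditions for a steered-pulling ensemble on a 1-D surrogate system.

    Units: kcal/mol, Å, ps, K. ``pull_speed`` is in Å/ns (the field
    convention for steering speeds); ``friction`` is the Langevin collision
    rate γ in 1/ps, combined with the reduced ``mass`` into the overdamped
    drag ζ = mγ. The default spring constant (100 kcal/mol/Å²) puts the
    guide in the stiff-spring regime where accumulated guide work
    approximates the free-energy profile.
    """

    potential: object
    end_position: float
    start_position: float = 0.0
    spring_constant: float = 100.0
    pull_speed: float = 1.0          # Å/ns
    temperature: float = 310.0
    friction: float = 50.0           # 1/ps
    mass: float = 1.0                # (kcal/mol) ps² / Å²
    timestep: float = 0.001          # ps
    n_replicates: int = 60
    seed: int = 0
    equilibration_steps: int = 5000
    target_save_points: int = 200

    def __post_init__(self) -> None:
        if self.end_position <= self.start_position:
            raise ValueError("end position must exceed start position")
        if self.spring_constant <= 0 or self.pull_speed <= 0:
            raise ValueError("spring constant and pull speed must be positive")
        if self.timestep <= 0 or self.friction <= 0 or self.mass <= 0:
            raise ValueError("timestep, friction and mass must be positive")
        zeta = self.friction * self.mass
        k_total = self.spring_constant + self.potential.max_curvature()
        limit = min(2.0 / self.friction, 2.0 * zeta / k_total)
        if self.timestep >= limit:
            raise IntegratorInstabilityError(
                f"timestep {self.timestep} ps exceeds the stability limit "
                f"{limit:.4g} ps for friction {self.friction}/ps and total "
                f"stiffness {k_total:.4g} kcal/mol/Å²")

    @property
    def zeta(self) -> float:
        return self.friction * self.mass

    @property
    def kT(self) -> float:
        return thermal_energy(self.temperature)


def generate_pulling_ensemble(spec: PullingSpec, label: str = "") -> WorkEnsemble:
    """Simulate an ensemble of steered pulls and collect W(λ) curves.

    Each replicate is an overdamped Langevin particle in U(q), coupled to a
    harmonic guide translating from λ₀ to λ_end at the pull speed; the
    external work of the guide is accumulated per step. The analytic
    stiff-spring ground truth U(λ_end) − U(λ₀) is recorded on the ensemble.
    A guide too soft to track λ (mean lag > 3 thermal widths) is warned.
    """
    v_ps = spec.pull_speed * 1e-3   # Å/ns -> Å/ps
    span = spec.end_position - spec.start_position
    n_steps = int(round(span / (v_ps * spec.timestep)))
    stride = max(1, n_steps // max(spec.target_save_points - 1, 1))
    n_steps = stride * int(np.ceil(n_steps / stride))
    n_save = n_steps // stride + 1
    lam = spec.start_position + v_ps * spec.timestep * stride * np.arange(n_save)

    pot = spec.potential
    if pot.pot_id == 3:
        tab_q, tab_f = pot.q, pot.force_table
    else:
        tab_q = np.zeros(2)
        tab_f = np.zeros(2)
    p0, p1 = pot.params

    seeds = np.random.SeedSequence(spec.seed).generate_state(spec.n_replicates) % (2 ** 31)
    work = np.empty((spec.n_replicates, n_save))
    lag_sum = 0.0
    for i in range(spec.n_replicates):
        w, q = _pull_replicate(int(seeds[i]), spec.equilibration_steps, n_steps,
                               spec.timestep, spec.start_position, v_ps,
                               spec.spring_constant, spec.zeta, spec.kT,
                               pot.pot_id, float(p0), float(p1),
                               np.asarray(tab_q, dtype=float),
                               np.asarray(tab_f, dtype=float), stride, n_save)
        work[i] = w
        lag_sum += float(np.mean(lam - q))
    mean_lag = lag_sum / spec.n_replicates
    thermal_width = np.sqrt(spec.kT / spec.spring_constant)
    if mean_lag > 3.0 * thermal_width:
        warnings.warn(f"guide spring too soft to track the schedule "
                      f"(mean lag {mean_lag:.3g} Å > 3 thermal widths)",
                      stacklevel=2)
    analytic = float(pot.energy(lam[-1]) - pot.energy(lam[0]))
    return WorkEnsemble(lam=lam, work=work, temperature=spec.temperature,
                        label=label, analytic_delta_f=analytic)


def guide_free_energy_difference(potential, spring_constant: float,
                                 lam0: float, lam1: float, kT: float,
                                 half_width: float = 15.0) -> float:
    """Exact guide free-energy difference by numerical integration.

    F(λ) = −kT ln ∫ exp(−[U(q) + κ_s(q−λ)²/2]/kT) dq; the returned
    difference F(λ₁) − F(λ₀) is what a quasi-static stiff-spring pull
    measures, and converges to U(λ₁) − U(λ₀) as κ_s → ∞.
    """
    def f_of(lam: float) -> float:
        def boltz(q):
            u = float(potential.energy(q)) + 0.5 * spring_constant * (q - lam) ** 2
            return np.exp(-u / kT)
        z, _ = quad(boltz, lam - half_width, lam + half_width, limit=200)
        return -kT * np.log(z)
    return f_of(lam1) - f_of(lam0)


# ---------------------------------------------------------------------------
# stopped-flow traces
# ---------------------------------------------------------------------------

@dataclass
class StoppedFlowSpec:
    """Forward model of an ATP/ADP competition stopped-flow experiment.

    Defaults encode the study's mixing conditions: 25 µM ATP against the
    [ADP] series 0–640 µM. ``k0`` is the zero-ADP fast-phase rate
    (ATP-induced actomyosin dissociation at 25 µM ATP); the fast rate at
    each [ADP] follows k_f = k₀/(1 + [ADP]/K_ADP). ``noise_sd`` defaults to
    1% of the total decay amplitude.
    """

    k_adp_true: float
    adp_concentrations: Sequence[float] = (0.0, 20.0, 40.0, 80.0, 160.0, 320.0, 640.0)
    k0: float = 100.0
    slow_rate: float = 1.5
    fast_amplitude: float = 0.7
    slow_amplitude: float = 0.15
    offset: float = 0.1
    noise_sd: float | None = None
    n_points: int = 2000
    duration: float = 1.0
    atp_um: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k0 <= 0 or self.slow_rate <= 0 or self.k_adp_true <= 0:
            raise ValueError("all rates and K_ADP must be positive")
        if any(c < 0 for c in self.adp_concentrations):
            raise ValueError("ADP concentrations must be non-negative")
        if self.noise_sd is None:
            self.noise_sd = 0.01 * (self.fast_amplitude + self.slow_amplitude)
        kf_min = self.k0 / (1.0 + max(self.adp_concentrations) / self.k_adp_true)
        if kf_min <= self.slow_rate:
            raise ValueError("fast phase must stay faster than the slow phase "
                             "at every [ADP] (phases not separable)")

    def fast_rate(self, adp_um: float) -> float:
        return self.k0 / (1.0 + adp_um / self.k_adp_true)


def wt_stopped_flow_spec(seed: int = 0, **kwargs) -> StoppedFlowSpec:
    """Study conditions with the wild-type ground-truth affinity (46.46 µM)."""
    return StoppedFlowSpec(k_adp_true=46.46, seed=seed, **kwargs)


def g256e_stopped_flow_spec(seed: int = 0, **kwargs) -> StoppedFlowSpec:
    """Study conditions with the mutant ground-truth affinity (32.82 µM)."""
    return StoppedFlowSpec(k_adp_true=32.82, seed=seed, **kwargs)


def generate_stopped_flow_traces(spec: StoppedFlowSpec) -> list[FluorescenceTrace]:
    """One noisy trace per [ADP]; the zero-ADP trace is single-exponential
    (slow amplitude 0), matching the experimental fitting convention."""
    rng = np.random.default_rng(spec.seed)
    t = np.linspace(0.0, spec.duration, spec.n_points)
    traces = []
    for adp in spec.adp_concentrations:
        kf = spec.fast_rate(adp)
        a_s = 0.0 if adp == 0 else spec.slow_amplitude
        clean = (spec.fast_amplitude * np.exp(-kf * t)
                 + a_s * np.exp(-spec.slow_rate * t) + spec.offset)
        signal = clean + rng.normal(0.0, spec.noise_sd, size=t.size)
        trace = FluorescenceTrace(time=t.copy(), signal=signal, adp_um=float(adp),
                                  atp_um=spec.atp_um)
        if adp > 0 and kf < 3.0 * spec.slow_rate:
            trace.warnings.append("phases separated by < 3x: fit identifiability "
                                  "is weak at this [ADP]")
        traces.append(trace)
    return traces


# ---------------------------------------------------------------------------
# force traces
# ---------------------------------------------------------------------------

@dataclass
class ForceTraceSpec:
    """Piecewise ground-truth model of a myofibril activation/relaxation trace.

    baseline → exponential rise (k_ACT) to steady-state force F_ss →
    plateau → linear slow relaxation of slope −k_REL,slow·F_ss for
    t_REL,slow → exponential fast relaxation (k_REL,fast) to baseline.
    ``noise_sd`` defaults to 2% of F_ss. Rates in 1/s, times in s, force in
    instrument units.
    """

    f_ss: float = 100.0
    k_act: float = 3.0
    k_rel_slow_true: float = 0.5
    t_rel_slow_true: float = 0.2
    k_rel_fast_true: float = 8.0
    baseline: float = 5.0
    activation_time: float = 0.5
    relaxation_time: float = 4.0
    duration: float | None = None
    noise_sd: float | None = None
    sample_rate: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relaxation_time <= self.activation_time:
            raise ValueError("relaxation must follow activation")
        for r in (self.k_act, self.k_rel_slow_true, self.k_rel_fast_true):
            if r <= 0:
                raise ValueError("all rates must be positive")
        if self.t_rel_slow_true <= 0:
            raise ValueError("slow-phase duration must be positive")
        if self.k_rel_slow_true * self.t_rel_slow_true >= 1.0:
            raise ValueError("k_REL,slow x t_REL,slow must be < 1 so force "
                             "stays positive through the linear phase")
        if self.noise_sd is None:
            self.noise_sd = 0.02 * self.f_ss
        if self.duration is None:
            self.duration = (self.relaxation_time + self.t_rel_slow_true
                             + 6.0 / self.k_rel_fast_true + 0.5)


def adp_condition(spec: ForceTraceSpec, **overrides) -> ForceTraceSpec:
    """Elevated-ADP preset: both relaxation rates halved and the slow-phase
    duration doubled, with activation slowed ~30% — the qualitative effects
    of 50% ADP replacement encoded as ground-truth parameter changes."""
    params = dict(
        f_ss=spec.f_ss, k_act=0.7 * spec.k_act,
        k_rel_slow_true=0.5 * spec.k_rel_slow_true,
        t_rel_slow_true=2.0 * spec.t_rel_slow_true,
        k_rel_fast_true=0.5 * spec.k_rel_fast_true,
        baseline=spec.baseline, activation_time=spec.activation_time,
        relaxation_time=spec.relaxation_time, noise_sd=spec.noise_sd,
        sample_rate=spec.sample_rate, seed=spec.seed,
    )
    params.update(overrides)
    return ForceTraceSpec(**params)


def generate_force_trace(spec: ForceTraceSpec,
                         condition: dict | None = None) -> ForceTrace:
    """Realize the piecewise trace with Gaussian noise and event markers."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sample_rate)) + 1
    t = np.arange(n) / spec.sample_rate
    f = np.full(n, spec.baseline)

    t_act, t_rel = spec.activation_time, spec.relaxation_time
    rise = (t >= t_act) & (t < t_rel)
    f[rise] = spec.baseline + spec.f_ss * (1.0 - np.exp(-spec.k_act * (t[rise] - t_act)))
    f_onset = spec.baseline + spec.f_ss * (1.0 - np.exp(-spec.k_act * (t_rel - t_act)))

    t_break = t_rel + spec.t_rel_slow_true
    lin = (t >= t_rel) & (t < t_break)
    f[lin] = f_onset - spec.k_rel_slow_true * spec.f_ss * (t[lin] - t_rel)
    f_break = f_onset - spec.k_rel_slow_true * spec.f_ss * spec.t_rel_slow_true

    tail = t >= t_break
    f[tail] = spec.baseline + (f_break - spec.baseline) * np.exp(
        -spec.k_rel_fast_true * (t[tail] - t_break))

    if spec.noise_sd > 0:
        f = f + rng.normal(0.0, spec.noise_sd, size=n)
    return ForceTrace(time=t, force=f,
                      events=[("activate", t_act), ("relax", t_rel)],
                      condition=dict(condition or {}))


# ---------------------------------------------------------------------------
# toy trajectories
# ---------------------------------------------------------------------------

@dataclass
class ResidueSpec:
    """A pseudo-residue: atom names/elements plus nonbonded parameters."""

    resname: str
    atoms: list  # of (name, element) tuples
    charges: Sequence[float] | None = None
    sigma: float = 3.0
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("residue needs at least one atom")
        if self.charges is None:
            self.charges = [0.0] * len(self.atoms)
        if len(self.charges) != len(self.atoms):
            raise ValueError("one charge per atom required")


@dataclass
class DihedralState:
    """A ligand torsion state: mean angle per rotatable torsion (degrees)
    and a shared von Mises concentration (None or inf = locked exactly)."""

    means: Sequence[float]
    kappa: float | None = None


@dataclass
class ContactInterval:
    """Half-open frame interval [start, stop) with an in/out-of-contact state."""

    start: int
    stop: int
    in_contact: bool = True


@dataclass
class ToyTrajectorySpec:
    """Blueprint for a bead "pocket + ligand" trajectory.

    ``contact_schedule`` maps residue-index pairs to intervals during which
    the pair is (or is explicitly not) in heavy-atom contact; unlisted
    frames default to no contact. ``ligand_atoms`` must number ≥ 4 so every
    requested torsion is computable; a 5-atom ligand exposes two torsions
    for 2-D map tests. ``state_sequence`` gives the torsion state per frame
    interval; alternatively ``state_probs`` samples states i.i.d. under the
    seed.
    """

    n_frames: int
    residues: list
    ligand_atoms: list = field(default_factory=lambda: [
        ("L1", "P"), ("L2", "O"), ("L3", "C"), ("L4", "C"), ("L5", "N")])
    ligand_charges: Sequence[float] | None = None
    ligand_sigma: float = 3.0
    ligand_epsilon: float = 0.1
    dihedral_states: list = field(default_factory=lambda: [DihedralState(means=(60.0, 180.0))])
    state_sequence: list | None = None   # list of (start, stop, state_idx)
    state_probs: Sequence[float] | None = None
    contact_schedule: dict = field(default_factory=dict)
    contact_distance: float = 3.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise ValueError("need at least one frame")
        if len(self.ligand_atoms) < 4:
            raise ValueError("ligand needs >= 4 atoms so a torsion is computable")
        if self.ligand_charges is None:
            self.ligand_charges = [0.0] * len(self.ligand_atoms)
        for pair, intervals in self.contact_schedule.items():
            if len(pair) != 2 or pair[0] == pair[1]:
                raise ValueError(f"invalid residue pair {pair!r}")
            for iv in intervals:
                if not (0 <= iv.start < iv.stop <= self.n_frames):
                    raise ValueError(f"interval {iv} outside [0, {self.n_frames})")
            for a in intervals:
                for b in intervals:
                    if a.in_contact != b.in_contact and a.start < b.stop and b.start < a.stop:
                        raise ValueError(f"contradictory schedule for pair {pair}: "
                                         f"{a} overlaps {b}")


_TETRAHEDRAL = 109.47


def _place_chain_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                      bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Internal-coordinate (NeRF-style) placement of the next chain atom."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    # sign of the n-component fixes the handedness so the placed atom's
    # measured torsion equals +torsion_deg
    d_local = np.array([-bond * np.cos(angle),
                        bond * np.sin(angle) * np.cos(torsion),
                        -bond * np.sin(angle) * np.sin(torsion)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _ligand_frame(site: np.ndarray, torsions: Sequence[float],
                  n_atoms: int, bond: float = 1.5) -> np.ndarray:
    coords = np.zeros((n_atoms, 3))
    coords[0] = site
    coords[1] = site + np.array([bond, 0.0, 0.0])
    ang = np.radians(_TETRAHEDRAL)
    coords[2] = coords[1] + bond * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for k in range(3, n_atoms):
        tor = torsions[k - 3] if k - 3 < len(torsions) else 180.0
        coords[k] = _place_chain_atom(coords[k - 3], coords[k - 2], coords[k - 1],
                                      bond, _TETRAHEDRAL, tor)
    return coords


def generate_toy_trajectory(spec: ToyTrajectorySpec) -> Trajectory:
    """Build coordinate frames realizing the contact and torsion schedules.

    Geometry: each residue sits at a home site 30 Å from its neighbours
    (far beyond the 5 Å contact cutoff). Each scheduled contact pair owns a
    private rendezvous site, 40 Å from every other; during in-contact
    frames one designated heavy atom from each partner meets there at the
    contact distance, guaranteeing the schedule is reproduced exactly by a
    min-heavy-atom-distance criterion. The ligand is an internal-coordinate
    chain at its own site whose rotatable torsions follow the requested
    state schedule (von Mises noise about the state means, or locked)."""
    rng = np.random.default_rng(spec.seed)
    n_res = len(spec.residues)
    pairs = sorted((tuple(sorted(p)) for p in spec.contact_schedule), key=tuple)

    # slot assignment: which atom of each residue serves each pair
    slot: dict[tuple, dict[int, int]] = {}
    used = {r: 0 for r in range(n_res)}
    for p in pairs:
        slot[p] = {}
        for r in p:
            if r >= n_res:
                raise ValueError(f"pair {p} references residue {r} not in layout")
            used[r] += 1
            idx = used[r]  # atom 0 stays home as the residue anchor
            if idx >= len(spec.residues[r].atoms):
                raise ValueError(f"residue {r} needs more atoms to serve "
                                 f"{used[r]} contact pairs")
            slot[p][r] = idx

    # per-frame contact state
    orig_key = {tuple(sorted(p)): p for p in spec.contact_schedule}
    in_contact = {p: np.zeros(spec.n_frames, dtype=bool) for p in pairs}
    for p in pairs:
        for iv in spec.contact_schedule[orig_key[p]]:
            if iv.in_contact:
                in_contact[p][iv.start:iv.stop] = True

    # per-frame torsion state
    n_lig = len(spec.ligand_atoms)
    n_torsions = n_lig - 3
    state_idx = np.zeros(spec.n_frames, dtype=int)
    if spec.state_sequence is not None:
        for start, stop, s in spec.state_sequence:
            state_idx[start:stop] = s
    elif spec.state_probs is not None:
        state_idx = rng.choice(len(spec.dihedral_states), size=spec.n_frames,
                               p=np.asarray(spec.state_probs, dtype=float))

    # topology
    rows = []
    atom_offset = {}
    cursor = 0
    for r, res in enumerate(spec.residues):
        atom_offset[r] = cursor
        for k, (name, element) in enumerate(res.atoms):
            rows.append({"name": name, "element": element, "resid": r,
                         "resname": res.resname, "mass": 12.0,
                         "charge": float(res.charges[k]),
                         "sigma": res.sigma, "epsilon": res.epsilon})
            cursor += 1
    lig_offset = cursor
    for k, (name, element) in enumerate(spec.ligand_atoms):
        rows.append({"name": name, "element": element, "resid": n_res,
                     "resname": "LIG", "mass": 12.0,
                     "charge": float(spec.ligand_charges[k]),
                     "sigma": spec.ligand_sigma, "epsilon": spec.ligand_epsilon})
        cursor += 1
    topology = pd.DataFrame(rows)

    # geometry
    homes = {r: np.array([30.0 * r, 0.0, 0.0]) for r in range(n_res)}
    rendezvous = {p: np.array([0.0, 500.0 + 40.0 * i, 0.0])
                  for i, p in enumerate(pairs)}
    lig_site = np.array([-500.0, 0.0, 0.0])

    coords = np.zeros((spec.n_frames, cursor, 3))
    for f in range(spec.n_frames):
        for r, res in enumerate(spec.residues):
            for k in range(len(res.atoms)):
                coords[f, atom_offset[r] + k] = homes[r] + np.array([0.0, 0.8 * k, 0.0])
        for p in pairs:
            if in_contact[p][f]:
                site = rendezvous[p]
                lo, hi = p
                coords[f, atom_offset[lo] + slot[p][lo]] = site
                coords[f, atom_offset[hi] + slot[p][hi]] = site + np.array(
                    [spec.contact_distance, 0.0, 0.0])
        state = spec.dihedral_states[state_idx[f]]
        means = list(state.means) + [180.0] * max(0, n_torsions - len(state.means))
        if state.kappa is None or not np.isfinite(state.kappa):
            torsions = means[:n_torsions]
        else:
            torsions = [np.degrees(rng.vonmises(np.radians(m), state.kappa))
                        for m in means[:n_torsions]]
        coords[f, lig_offset:lig_offset + n_lig] = _ligand_frame(lig_site, torsions, n_lig)
    return Trajectory(coords=coords, topology=topology)
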