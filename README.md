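# myoadp

Analysis toolkit for studies of ADP release from the actomyosin complex —
the rate-limiting step coupling myosin's chemo-mechanical cycle to cardiac
muscle relaxation. Hypertrophic-cardiomyopathy mutations in β-cardiac
myosin (e.g. transducer-region substitutions such as G256E) can tighten
nucleotide binding, slow cross-bridge detachment and prolong relaxation;
quantifying that requires the same measurement connected across three
scales: molecular-dynamics trajectories of the nucleotide pocket,
stopped-flow kinetics of purified motors, and single-myofibril force
transients. `myoadp` implements the analysis machinery for all three,
plus synthetic-data generators with exact ground truth so every estimator
in the chain is testable end to end.

Intended users: structural biophysicists and muscle physiologists who have
trajectories, steered-pulling work logs, fluorescence transients or force
traces and want the standard descriptor and fitting pipeline in one
tested, scriptable package.

## What it computes

**Trajectory descriptors** (`myoadp.trajectory`) — RMSD after Kabsch
superposition, two-pass RMSF about the average structure, residue–residue
heavy-atom contact fractions (5 Å cutoff), salt-bridge persistence,
nucleotide torsion series (the six ADP angles θ₁…θ₆ are predefined),
2-D dihedral maps (5°×5° bins) with Gibbs conformational entropy
S = −R Σ pᵢ ln pᵢ (cal mol⁻¹ K⁻¹) and percent coverage, per-residue linear
interaction energies (Coulomb + Lennard-Jones), binding-pocket selection
at a 3 kT threshold, center-of-mass reaction coordinates, modal distances,
seed-frame harvesting and ligand occupancy grids.

**Nonequilibrium work analysis** (`myoadp.pulling`) — ensembles of steered
pulling work curves W(λ) reduced to free-energy profiles with the
Jarzynski estimator

    ΔF(λ) = −kT ln ⟨ exp(−W(λ)/kT) ⟩,

evaluated via log-sum-exp; mean-work profiles, Welch t-tests between
conditions, the nearest-to-profile representative replicate, and
90 %-presence contact-release timelines.

**Stopped-flow kinetics** (`myoadp.kinetics`) — single/double-exponential
fits of ATP-induced actomyosin-dissociation transients with multi-start
initialization, and the apparent ADP affinity K_ADP from the competitive
binding law

    k_rel = k_obs / k_obs,0 = 1 / (1 + [ADP]/K_ADP).

**Myofibril mechanics** (`myoadp.mechanics`) — steady-state force,
activation kinetics k_ACT, change-point decomposition of biphasic
relaxation into the early linear phase (normalized slope k_REL,slow,
duration t_REL,slow) and the fast exponential phase (k_REL,fast), and
type-II two-way ANOVA (genotype × solution) for unbalanced designs.

**Synthetic data** (`myoadp.synthetic`) — overdamped-Langevin pulling on
1-D potentials with analytic ΔF, competitive-inhibition fluorescence
decays, piecewise force traces and bead "pocket + ligand" trajectories
with prescribed contact and torsion-state schedules.

## Worked example

```python
import numpy as np
from myoadp import synthetic, experiments, mechanics

# 1. stopped-flow: simulate the 0-640 uM ADP competition series at 1% noise
#    with the wild-type ground-truth affinity, then refit it blind
spec = synthetic.wt_stopped_flow_spec(seed=7)
traces = synthetic.generate_stopped_flow_traces(spec)
fit = experiments.fit_binding_curve_from_traces(traces)
print(f"K_ADP = {fit.k_adp:.2f} uM (ground truth {spec.k_adp_true} uM)")

# 2. steered pulling: 60 replicates on a harmonic toy at three speeds
study = experiments.jarzynski_speed_study(speeds=(10.0, 1.0, 0.1),
                                          n_replicates=60, seed=7)
for v in (10.0, 1.0, 0.1):
    r = study[v]
    print(f"v = {v:4} A/ns   <W> = {r['mean_work']:.3f}   "
          f"dF_Jarzynski = {r['jarzynski']:.3f}   "
          f"dF_analytic = {r['analytic']:.3f} kcal/mol")

# 3. myofibril relaxation decomposition at 2% noise
trace = synthetic.generate_force_trace(synthetic.ForceTraceSpec(seed=7))
dec = mechanics.decompose_relaxation(trace)
print(f"k_REL,slow = {dec.k_rel_slow:.3f} /s   "
      f"t_REL,slow = {dec.t_rel_slow:.3f} s   k_REL,fast = {dec.k_rel_fast:.2f} /s")
```

Output:

```
K_ADP = 44.81 uM (ground truth 46.46 uM)
v = 10.0 A/ns   <W> = 2.917   dF_Jarzynski = 1.925   dF_analytic = 2.000 kcal/mol
v =  1.0 A/ns   <W> = 2.190   dF_Jarzynski = 2.085   dF_analytic = 2.020 kcal/mol
v =  0.1 A/ns   <W> = 2.004   dF_Jarzynski = 1.989   dF_analytic = 2.020 kcal/mol
k_REL,slow = 0.481 /s   t_REL,slow = 0.183 s   k_REL,fast = 7.74 /s
```

The affinity refit lands within a few percent of the truth; mean work
exceeds ΔF at every speed (second law) with the excess shrinking as the
pull slows, while the Jarzynski estimate stays near the analytic value;
and the relaxation decomposition recovers the generator's parameters
(0.5 /s, 0.2 s, 8 /s) to within the noise.

A command-line interface mirrors the library: `myoadp make-synthetic`,
`analyze-traj`, `jarzynski`, `fit-stoppedflow`, `fit-kadp`,
`analyze-myofibril`, `compare-mechanics` and `run-pipeline` (an end-to-end
seeded demo writing TSV/JSON outputs plus a hash manifest).

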