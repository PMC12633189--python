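# Methods

This note records the models implemented in `myoadp`, the defaults and
units, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Units and constants

Energies kcal/mol, lengths Å, times ps (simulation) or s (kinetics),
temperatures K. kT = 0.6160 kcal/mol at the 310 K simulation temperature;
entropies use R = 1.9872 cal mol⁻¹ K⁻¹; the Coulomb constant is
332.0636 kcal·Å·mol⁻¹·e⁻².

## Trajectory descriptors

The `Trajectory` container is an (n_frames, n_atoms, 3) Å array plus a
per-atom pandas table (name, element, residue, mass, and optionally
partial charge and LJ σ/ε). Heavy atoms are all non-hydrogens.

* **RMSD** — each frame is superposed on the reference by unweighted
  Kabsch (SVD with proper-rotation correction) over the selection before
  the RMSD is taken over that selection.
* **RMSF** — two-pass: frames are aligned to a provisional average
  (seeded from frame 0), the average is recomputed from aligned frames,
  frames are re-aligned to it, and per-atom RMS deviations from the final
  mean are reported.
* **Contacts** — residues are in contact in a frame iff any heavy-atom
  pair is within the cutoff (default 5 Å); fractions are per-pair means
  over frames. Salt bridges use a 4.0 Å cutoff between side-chain
  charged-group N/O atoms (named atoms for standard residues, falling
  back to charge-annotated N/O); 4.0 Å is the conventional
  structural-biology criterion and is a package decision.
* **Torsions** — the signed atan2 formula, degrees on (−180, 180];
  collinear triplets yield NaN rather than an arbitrary angle. The six
  ADP torsions (phosphate tail, ribose linkage, glycosidic angle) ship
  predefined.
* **Dihedral maps, entropy, coverage** — joint 2-D histograms on
  [−180, 180)² with bin widths dividing 360 (default 5°, 72×72). Entropy
  is the Gibbs formula −R Σ p ln p over occupied bins (0·ln 0 ≡ 0), so it
  ranges from 0 (one bin) to R ln N_bins (uniform). Coverage counts bins
  with ≥ 1 sample, with no density threshold — the simplest reading of
  "percent of the map sampled". Published per-map entropy values obtained
  with other estimators are not directly comparable and are not used as
  targets here.
* **Interaction energies** — per-frame pairwise vacuum Coulomb plus
  Lennard-Jones 12-6 with Lorentz–Berthelot combining, averaged over
  frames; electrostatic, van der Waals and combined are all reported. A
  distance cutoff is exposed as an option (production MD typically uses
  10 Å) but defaults to none, which is exact on small toy systems.
  Binding-pocket membership takes residues whose |combined| energy with
  any ligand group reaches 3 kT (kT at 310 K).
* **Reaction coordinate** — mass-weighted COM distance per frame. The
  modal distance is the center of the most-populated 0.1 Å histogram bin,
  ties resolving to the smaller distance (the bin width matches the
  0.1 Å seed-selection tolerance). Seed frames are those within 0.1 Å of
  the target distance, thinned evenly by frame index to at most 20 per
  replicate — even spacing avoids harvesting temporally clustered,
  correlated structures.
* **Occupancy grids** — voxel visit counts (0.5 Å default spacing) on a
  pre-aligned trajectory; the display iso-level is mean + 2 SD of the
  nonzero voxels (equal to the single count when only one voxel is
  occupied).

## Langevin pulling surrogate

The steered-MD stage of the original workflow cannot be reproduced at
desk scale, and is not: the generator exists to validate the work/free-
energy estimators, not to simulate myosin. It integrates one overdamped
coordinate q in a 1-D potential U(q) (flat, harmonic, double-well or
tabulated) coupled to a harmonic guide of stiffness κ_s whose center
moves λ(t) = λ₀ + vt:

    dq = [−U′(q) + κ_s(λ − q)] dt/ζ + √(2 kT dt/ζ) dW,
    W += κ_s(λ − q) · v · dt.

Euler–Maruyama with default dt = 0.001 ps; specs are rejected when dt
exceeds the stability limit min(2/γ, 2ζ/(κ_s + max|U″|)). The drag is
ζ = mγ with reduced mass m = 1 (kcal/mol)·ps²/Å² and collision rate
γ = 50 ps⁻¹, giving D = kT/ζ ≈ 1.2×10⁻⁶ cm²/s — the order of magnitude
of small-molecule diffusion in water, so the study speeds (0.1–10 Å/ns)
span the near-equilibrium to strongly dissipative regimes. κ_s defaults
to 100 kcal/mol/Å², stiff enough that the guide work approximates the
free-energy profile (thermal width √(kT/κ_s) ≈ 0.08 Å); ensembles whose
mean guide lag exceeds 3 thermal widths are flagged as soft-spring runs.
The recorded ground truth is the stiff-spring limit U(λ_end) − U(λ₀);
`guide_free_energy_difference` also evaluates the exact finite-κ_s value
by numerical quadrature for oracle checks. Pull speeds are given in Å/ns
(the field convention); per-replicate seeds derive from one SeedSequence
so ensembles are bit-reproducible.

The Jarzynski reduction uses log-sum-exp, so large work values cannot
underflow; a single-replicate ensemble degenerates to ΔF = W with a
warning. The "representative trajectory" is operationalized as the
replicate minimizing the L2 distance between its work curve and the
profile — it designates a real structure series to display, which an
exponentially weighted average would not. Condition comparisons use
Welch's (unequal-variance) t-test on final-λ works, the conservative
choice when variance equality is unverified. Known limitation: with
realistic replicate counts the Jarzynski estimate at strongly dissipative
speeds is biased high (few low-work tails are sampled); the tests
therefore validate it in the near-equilibrium regime and only check
bounds and monotonicity elsewhere. Bidirectional estimators (Crooks/BAR)
are out of scope.

## Stopped-flow forward model and fitting

Generated transients follow
A_f e^(−k_f t) + A_s e^(−k_s t) + C + ε, ε ~ N(0, σ), with the fast
phase obeying competitive inhibition k_f = k₀/(1 + [ADP]/K_ADP) and the
zero-ADP trace single-exponential (slow amplitude zero), matching the
experimental fitting convention. Defaults encode the study conditions:
[ADP] ∈ {0, 20, 40, 80, 160, 320, 640} µM against 25 µM ATP; ground-truth
affinities 46.46 µM (wild type) and 32.82 µM (mutant). k₀ = 100 s⁻¹ is
the expected ATP-induced dissociation rate at 25 µM ATP (second-order
ATP binding ≈ 4 µM⁻¹s⁻¹); the slow phase is 1.5 s⁻¹ with amplitudes
0.7/0.15 and offset 0.1, keeping the phases separable at the highest
[ADP] (6.8 vs 1.5 s⁻¹); "1% noise" means σ = 0.01·(A_f + A_s). Traces
are 2000 points over 1 s. Specs violating phase separability are
rejected; marginal (< 3×) separation is recorded in trace metadata.

Exponential fits are unweighted nonlinear least squares (no weighting
scheme is standard for these transients). The double-exponential fit is
initialization-sensitive, so the tail slow phase is peeled off first for
a data-driven start, with a log-spaced grid of rate pairs as fallback and
best-residual selection; phases are ordered fast > slow, a rate ratio
below 3 triggers an identifiability warning, and rates collapsing onto
each other (ratio < 1.05) are reported as the single-exponential solution
with zero slow amplitude. The binding curve k_rel([ADP]) is fit with the
one-parameter hyperbola through (0, 1) — the intercept is a constraint,
not a free offset, because k_rel is defined as a ratio. With replicate
curves the SE of K_ADP is the SD of per-replicate fits (the experimental
n = 4 convention); otherwise it comes from the fit curvature.

## Force-trace model and decomposition

Generated traces are piecewise: baseline; exponential rise
F_ss(1 − e^(−k_ACT(t−t_act))); plateau; from the relaxation switch a
linear segment of slope −k_REL,slow·F_ss lasting t_REL,slow; then
exponential decay to baseline at k_REL,fast. Defaults (F_ss = 100,
k_ACT = 3 s⁻¹, k_REL,slow = 0.5 s⁻¹, t_REL,slow = 0.2 s,
k_REL,fast = 8 s⁻¹, 1 kHz sampling, σ = 0.02·F_ss) are typical of
β-myosin myofibrils at 15 °C; the invariant k_REL,slow·t_REL,slow < 1
keeps force positive through the linear phase. The elevated-ADP preset
halves both relaxation rates, doubles the slow-phase duration and slows
activation ~30% — it encodes the qualitative product-inhibition effects
as ground-truth parameter changes, not mechanistic chemistry.

Decomposition excludes a 5 ms solution-switch dead time from every fit
window. The slow→fast transition is found by exhaustive scan over sample
candidates in (relax + 10 ms, relax + 1 s): each candidate is scored by
the SSE of a linear fit before it plus an exponential fit after it
(decay to the pre-activation baseline; parameters from an
amplitude-weighted log-linear regression, SSE evaluated in linear space),
and the global minimizer taken, first-on-ties. The scan objective is
deliberately closed-form so an independent oracle can reproduce it
exactly; the reported k_REL,fast is then refined by nonlinear least
squares at the selected transition. k_REL,slow is the |slope| divided by
the fitted force at the relaxation onset, yielding 1/s and making the
statistic invariant to force units (whether published slow-phase rates
are amplitude-normalized is ambiguous; this affects absolute values, not
group contrasts). Traces whose best interior split does not beat a
single-segment fit are flagged monophasic; traces whose onset force is
within 3× the baseline noise are rejected as unresolvable. Steady-state
force is the baseline-subtracted mean over the 0.5 s before relaxation.

Group comparison uses type-II sums-of-squares two-way ANOVA
(genotype × solution) via statsmodels — well-defined for the unbalanced
group sizes typical of per-myofibril data (e.g. 15 vs 13) — with Welch
t-tests per solution (Holm-corrected) as pairwise contrasts. Sarcomere-
length/cross-sectional normalization and calcium-solution chemistry are
out of scope.

## Synthetic toy trajectories

The bead "pocket + ligand" generator realizes exact descriptor ground
truths: each pseudo-residue sits 30 Å from its neighbours; every
scheduled contact pair owns a private rendezvous site 40 Å from all
others where one designated heavy atom from each partner meets at 3.5 Å
during in-contact frames — so a min-heavy-atom-distance criterion
reproduces the schedule exactly, with no accidental contacts. The ligand
is an internal-coordinate chain (1.5 Å bonds, tetrahedral angles) whose
rotatable torsions follow a prescribed state schedule, locked exactly or
von Mises-dispersed. Schedules that assert both contact and no-contact
for one pair in one frame are rejected. What these toys do **not**
emulate: bonded geometry, excluded volume, solvent, correlated motions,
periodic boundaries — so passing descriptor tests certifies the
estimators' arithmetic, not their robustness to real-trajectory artifacts
(imaging, alignment drift), which the package assumes handled upstream.

## Pipeline and reproducibility

The `run-pipeline` command executes five stages (pulling, trajectory,
stopped-flow, mechanics, summary) from a JSON configuration validated
before anything runs; an explicit integer seed is mandatory, per-stage
seeds derive from it via SeedSequence, numeric tables are written with 6
significant digits, and the manifest records stage list, seeds, SHA-256
output hashes and the package version. Reruns under the same seed are
byte-identical. The default demo completes in well under a minute on one
CPU.

## Problem sizes used in self-validation

The recovery experiments run at deliberately modest sizes chosen as the
package's own test conditions: affinity recovery uses 20 simulated
experiments (7 traces each) per genotype at 1% noise; the pulling study
uses 60 replicates per speed at speeds {10, 1, 0.1} Å/ns over a 2 Å pull
with dt = 0.01 ps (stability-checked; the finer 1 fs default matters only
for stiffer systems); relaxation recovery uses 100 random parameter sets
at 2% noise. Under these conditions the median recovered K_ADP sits
within a few percent of truth, the slow-pull Jarzynski estimate lands
within 0.05 kT of the analytic value, and all three relaxation parameters
recover with median errors below 7%.
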