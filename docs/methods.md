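# Methods

This note documents the models behind `antiport`, the defaults that matter,
what the synthetic systems do and do not emulate, and the numerical choices
made where the design was genuinely open.

## Collective variables and model landscapes

The package analyzes transport in terms of one or two collective variables
(CVs): the z-displacement (along the membrane normal) of each chloride ion
from the center of the transporter's central cavity, in nanometers,
positive toward the extracellular side.  Exchanging the two ions leaves the
physics unchanged, so 2D landscapes carry an explicit permutation symmetry.

Ground-truth landscapes are sums of Gaussian terms
`V(x) = Σ A_k exp(−Σ_d (x_d − c_kd)²/(2 w_kd²))` (energies in kT), with
reflecting walls at the CV bounds.  Four presets cover the regimes of
interest:

* `flat` — identity case for sampler calibration;
* `double_well_1d` — wells of 6 kT at ±1 nm (width 0.3 nm); the planted
  barrier, `V(0) − V(±1) ≈ 5.95 kT`, is the recovery oracle;
* `wp_like` — the protonated-external-glutamate regime: a chain of three
  trap minima at fixed z₁ ≈ 1.2 nm and z₂ ∈ {0.55, 0, −0.55} nm with depths
  12/13/14 kT (plus mirror images), and an 8 kT ridge blocking the
  concerted diagonal exit.  Escape from the deepest trap costs > 10 kT.
* `wd_like` — the regime after the protonation switch: a dense ramp of
  increasingly deep on-diagonal Gaussians making the concerted two-ion
  movement monotonically downhill from (1,1) to (−1.5,−1.5) nm.  The ramp
  extends past the channel end so no spurious uphill stretch appears inside
  it.

These presets are qualitative stand-ins calibrated to the stated topology
(trap chain, high exit barrier, downhill diagonal), not fits to any
published surface.

## Dynamics

Walkers follow overdamped Euler–Maruyama Langevin dynamics
`x' = x − (D/kT) ∇(V + V_bias) dt + √(2 D dt) η`, reflecting at the CV
walls.  Defaults D = 0.01 nm²/ps and dt = 0.2 ps keep the stiffness
`D·dt·|V''|` well below one on the preset wells; the benchmark runs use
D = 0.02 nm²/ps for faster mixing (stiffness ≈ 0.27 on the double well).
For the discretized harmonic oscillator the stationary variance is
`2 D dt / (a (2 − a))` with `a = D dt k / kT`, which the equipartition test
uses as its exact oracle.

## Well-tempered metadynamics

Hills are Gaussians of width σ (default 0.25 nm) deposited every `stride`
steps (default 500) with the well-tempered height rule
`W = W₀ exp(−V_bias(s)/((γ−1) kT))`, W₀ = 0.5 kT and γ = 10 by default.
These engine defaults are package choices for the desk-scale runs, not
values taken from any production study.  All walkers of a chain share one
append-only hill list; at a deposition step walkers deposit sequentially,
so each sees the hills its peers just added.

**Reflecting-wall images.**  With reflecting CV walls the stationary bias
must satisfy a zero-flux condition at the boundary; plain kernel sums
under-fill the edges (the kernel mass beyond the wall is lost) and leave
1–5 kT artifacts in the outermost ~2σ of the domain.  Bias evaluation
therefore adds per-dimension mirror images of each kernel at the walls,
pruned beyond 5σ.  Corner (cross-dimension) images are neglected; their
contribution is second-order in the image overlap.  Image bookkeeping
travels with the HILLS header so a written bias re-reads identically.

**Chain averaging and restart.**  Two chains merge into
`B*(z₁,z₂) = ¼[B_A(z₁,z₂) + B_A(z₂,z₁) + B_B(z₁,z₂) + B_B(z₂,z₁)]`,
realized by emitting every input hill at quarter height together with its
permuted twin — the output stays a hill list, so restarts remain hill-based.
A restarted run continues from the averaged bias (the well-tempered memory
is not reset) with the initial hill height raised by the conventional
factor of four.  The height of the first restart hill equals exactly 4·W₀
only where the accumulated bias is numerically zero; tests evaluate it in a
bias-free corner.

**1D proton-transfer surrogate.**  The `qmmm_like` schedule (0.5 kcal/mol
hills, 0.3 Å spread, every 5 steps, kT in kcal/mol at 298 K) emulates a
constant-height deposition schedule; it is implemented as well-tempered
metadynamics with a large bias factor (γ = 50), under which heights decay
by at most a few percent over a desk-scale run.  No quantum region exists
anywhere in the package: the proton-transfer profile is an analytic 1D
surface.

## Free-energy estimation and analysis

The estimator is the final-bias well-tempered relation
`F(s) = −γ/(γ−1)·V_bias(s)`, shifted to min-zero (only relative free
energies are meaningful; no time-dependent c(t) correction is applied, the
two being asymptotically equivalent).  Symmetrization averages F with its
transpose and re-offsets; it is exact (machine precision) and idempotent.

Minima are strict interior grid points below all 8 (2D) or 2 (1D)
neighbors; exact plateaus count only when their connected flat patch is
enclosed by strictly higher cells and resolve to the lowest lexicographic
index (flagged).  Points on the domain boundary never qualify: a dip
pinned against the CV box wall is an artifact of the bounded toy domain.
Basin depth is topographic prominence — the minimax barrier to any strictly
lower cell — computed with the same Dijkstra-style relaxation used for
barriers.  `mep_barrier` relaxes path cost `max(F)` over 8-connected grid
moves; the saddle is reported relative to F(start), so forward and reverse
barriers share one minimax level: `mep(s,e) = mep(e,s) + F(e) − F(s)`.

Block profiles follow the averaged-intermediate-profile practice: the hill
sequence is cut at kernel-count checkpoints (nine blocks of 2,500 kernels
by default), a profile is estimated from the cumulative bias at each
checkpoint, and the mean and pointwise standard deviation across
checkpoints quantify convergence.  For a converged run the late
checkpoints coincide and the spread collapses; in the saturated limit
(later kernels carry zero height) it vanishes identically.  Because a
single stochastic run fluctuates, the convergence tests assert a uniform
late-versus-early reduction in checkpoint drift rather than strict
per-checkpoint monotonicity.

## Reweighting and conditional maps

Frame weights use the time-independent final-bias scheme
`w ∝ exp(V_bias,final(cv)/kT)`; a `last_half_only` flag drops the first
half of the run, where the rapidly growing bias makes early frames
over-weighted.  The 2D reweighting benchmark is a shallow (~3 kT)
exchange-symmetric three-well surface on (−1.5, 1.5)² nm, chosen so a
4-walker, 10⁵-step run converges on a desk budget; the Jensen–Shannon
divergence between the reweighted histogram and the analytic Boltzmann
density over a 30×30 grid is ~0.015 at 2·10⁵ frames.

Conditional maps bin frames on half-open CV intervals `[lo, hi)` (frames at
or beyond the last edge are discarded and counted), rank frames per bin by
weight with ties broken by earlier time, keep up to k = 10 representatives,
and average the observable unweighted across them.  The recovery guarantee
for a planted observable `f(cv) + N(0, σ²)` is the CLT bound `3σ/√k` per
bin — a 3-sigma statement, so across ~10² bins the binomially expected
handful of exceedances is tolerated and a 5-sigma cap guards every bin.
k-means clustering of representative structures delegates to scikit-learn
(k-means++, Lloyd iterations, seeded).

## Electrostatics and titration

The deprotonation potential replaces a grid Poisson–Boltzmann solver with a
closed-form screened-Coulomb scorer: with Δq the site's
deprotonated-minus-protonated charge differences,

ΔΔG = Σ_site Σ_env 332.06 · Δq_i q_j · exp(−κ r_ij) / (ε r_ij)  [kcal/mol],

where ε = 10 (a conventional effective permittivity for a buried site),
κ is the Debye constant for I = 0.15 M at 298 K
(κ² = 2 N_A e² I/(ε ε₀ k_B T); for water at ε = 78.5 this gives the
textbook 7.9 Å screening length), and the isolated model compound
contributes zero by construction.  Only deprotonation is scored — no proton
is ever placed — so the value is a deprotonation potential, a proxy that is
large exactly when the protonated site coordinates a nearby anion.  The
effective pKₐ is `pKₐ,ref + ΔΔG/(ln10·kT)` with pKₐ,ref = 4.25 for a
glutamate.  Because all Δq are negative, adding any negative environment
charge raises ΔΔG monotonically, and the score is exactly invariant under
rigid motions.

Constant-pH titration samples the two-state protonation indicator with
Metropolis flips at `ΔG(pH) = ln10·kT·(pKₐ − pH)` over eight pH windows
(default), then fits `f = 1/(1+10^{n(pKₐ−pH)})` by least squares.  At 10⁵
steps per window the fitted pKₐ lands within 0.1 of the planted value.

## Toy structures and water wires

Snapshots place the two gating carboxylates on the pore axis (their
hydrogen-bonding oxygens 11 Å apart by default, carboxyl C and second O
offset laterally), chlorides on ±x tracks at z = CV·10 Å, and optional
bulk waters.  Charges are simple clean sets (TIP3P-like waters, −1
chlorides, carboxylate states summing to 0/−1); both protonation-state
charge sets ride with the structure so the electrostatics module forms Δq
without re-deriving chemistry.

`plant_wire` inserts an evenly spaced donor→acceptor water chain between
the carboxylate oxygens, each water donating one O–H along the chain, and
switches the structure to the Grotthuss regeneration state: intracellular
site protonated (proton aimed at the first water), extracellular site
deprotonated.  A straight chain has no donor for its first hop otherwise,
and a retained extracellular proton would sit inside the wire.  Planting
fails loudly when the requested water count cannot span the gap with hop
lengths in [2.3, 3.5] Å.

Wire detection builds an undirected oxygen graph under the criteria
O–O ≤ 3.5 Å and D–H⋯A ≥ 120° (standard MD conventions; configurable) —
an edge requires at least one of the two oxygens to donate an explicit
hydrogen at a satisfying angle — and enumerates simple paths with at most
`max_waters` (default 3) interior water oxygens, shortest first.
Tightening either criterion can only remove wires.

## What the synthetic systems do not show

Passing these tests demonstrates the correctness of the estimators,
protocols and search algorithms — not anything about a real protein.  The
toys have no membrane, lipids, protein degrees of freedom, explicit
solvent dynamics, polarization, or quantum effects; the Langevin walkers
have no inertia; the electrostatic scorer is a uniform-dielectric
screened-Coulomb model, not a Poisson–Boltzmann solution; wire geometry is
idealized.  Conclusions about any specific transporter require real
trajectories as input, which the readers (HILLS/COLVAR/PDB + sidecar)
accept.

## Problem sizes and determinism

The default verification sizes are: 4 walkers × 2·10⁵ steps (1D recovery),
4 walkers × 10⁵ steps recording every step (2D reweighting, 2·10⁵ frames
in the analysis half), 8 × 10⁵ Metropolis steps (titration), 50 random
boxes plus planted 1/2/3-water wires (wire oracle), 10 random 20×20 grids
(minimax oracle), 20 random structures (electrostatics oracle).  Every
random draw flows from an explicit integer seed (per-walker streams are
spawned from (seed, chain, walker)), identical seeds give bit-identical
hill lists and outputs, and every written file carries the seed, a config
hash and the package version in its header plus a row-count footer that
readers verify.
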