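# Methods

## Model

`cgdna` folds DNA chains with a three-bead-per-nucleotide representation:
P (phosphate), C (sugar, C4') and N (base, N1 for pyrimidines / N9 for
purines).  Beads are spheres with van der Waals radii 1.9 / 1.7 / 2.2 A;
only P carries charge (-1 e).  The total energy is

    U = Ub + Ua + Ud + Uexc + Ubp + Ubs + Ucs + Uel

with harmonic bonds and angles, `k (1 - cos(phi - phi0))` dihedrals, WCA
excluded volume, Gaussian distance-and-orientation wells for Watson-Crick
pairing, base stacking and coaxial stacking, and a Debye-Hueckel screened
Coulomb term between reduced phosphate charges.  Temperature enters the
potential only through the electrostatics (dielectric, Debye length, and
condensation baseline), which is why replica exchange uses the generalized
criterion (below).

### Bonded terms and the two parameter sets

The bonded graph per nucleotide is P-C (side bead N on C) plus the C-P
link to the next residue; angles PCN, NCP, PCP, CPC and dihedrals PCPC,
CPCN, CPCP are scored.  Two complete parameter sets are shipped as YAML:

* **loop** (`data/bonded_loop.yaml`) — soft constants, equilibria chosen so
  that a deterministic reference chain (built by internal-coordinate
  placement, `cg_model.loop_reference_chain`) realizes exactly zero bonded
  energy.  Used for the whole chain during folding, so single-stranded
  regions stay flexible.
* **helix** (`data/bonded_helix.yaml`) — stiff constants with equilibria
  measured from the package's parametric ideal B-form duplex generator
  (rise 3.38 A, twist 36 deg, cross-pair N-N distance 8.91 A, cross-strand
  P-P width 17.8 A).  Applied only to currently base-paired residues
  during the final refinement stage, to regularize stems toward canonical
  geometry.  A bonded term uses the helix set only when every residue it
  touches is paired.

Nonbonded exclusions follow the usual 1-2/1-3/1-4 convention (pairs within
three bonds are omitted from Uexc), so the excluded volume does not fight
the bonded terms over the same coordinates; with this convention the ideal
duplex generator carries exactly zero repulsion and sits at a local
minimum of the full potential.

### Pairing, stacking, coaxial stacking

A pair (i, j) contributes `-eps * G(d) * w_i * w_j` with `G` a Gaussian in
the N-N distance centred at the generator's 8.91 A (width 2 A) and `w` a
smoothstep in the facing alignment of each base's C->N vector; at the
generator's geometry both factors are exactly 1, so the ideal pair scores
the full well depth.  Stacking rewards adjacent pairs (i,j),(i+1,j-1)
through the same kind of Gaussian in the pair-midpoint distance (centre
4.36 A), with dimer-step-specific depths ordered per nearest-neighbor
thermodynamics; the mean stacking-entropy penalty is folded into the
depths rather than carried as an explicit temperature term.  Coaxial
stacking applies the stacking form to the closest terminal-pair
combination of every two distinct stems, times a smoothstep in the
pair-axis alignment, so abutting stems across a junction are rewarded and
the term decays smoothly to zero as stems separate.

**Depth calibration.**  The supplementary parameter tables of the source
force-field lineage are not redistributable, so the depths here are the
package's own parameterization: relative magnitudes follow unified
nearest-neighbor dimer free energies (G-C pairs 1.5x A-T; CG/GC steps
deepest, TA weakest), and the overall scale was calibrated during
development so that a 12-nt four-G:C-pair stem-loop melts inside the
25-110 C replica ladder (folded at 25 C, molten by ~70 C).  That places
short-motif melting where the two-state analysis can see both branches of
the transition; absolute melting temperatures for other motifs inherit
the uncertainty of this single-scale calibration.

### Electrostatics

`Uel = sum_{i<j} Qi Qj e^2/(4 pi eps0 eps(T) rij) exp(-rij/lD)` with the
empirical pure-water permittivity polynomial
`eps(T) = 87.740 - 0.4008 T + 9.398e-4 T^2 - 1.410e-6 T^3` (T in C),
Bjerrum length `lB = e^2/(4 pi eps0 eps kB T)` (7.15 A at 25 C) and Debye
length from the full ionic strength including chloride counterions
(9.6 A at 0.1 M NaCl).  Reduced charges `Qi = 1 - fi` come from
counterion condensation: the chain-average neutralization is
`fbar = 1 - b/(nu lB)` with charge spacing `b = 4.4 A` (configurable), and
the per-phosphate values redistribute that average through a softmax in
the local reduced potential `phi_i = sum_j lB Qj exp(-rij/lD)/rij`
(exponent `-nu phi_i`, damped fixed-point iteration, damping 0.5,
tolerance 1e-4, 200 iterations max).  Where the proportional share would
exceed 1, beads are pinned at full neutralization and the excess is
redistributed over the rest (water-filling), so `0 <= fi <= 1` and
`sum fi = N fbar` hold simultaneously.  The sign of the exponent follows
the source formulation as printed; the opposite sign (condensation
enhanced where the potential is strongest) is physically arguable and
trivially switchable in `_solve_single_valence`.

Mixed Na+/Mg2+ solutions solve each valence separately and blend
`fi = x fi(1) + (1-x) fi(2)` with the tightly-bound-ion partition
`x = [Na+]/([Na+] + alpha [Mg2+])`,
`alpha = (8.1 - 64.8/N)(5.2 - ln [Na+])`; for chains shorter than nine
residues the first factor is non-positive and alpha clamps to zero with a
warning.  During sampling the charge state refreshes every 100 moves and
immediately on any pairing change or replica exchange, warm-started from
the previous solution.

## Sampling

Moves: chain pivots (one side of a random backbone bead rotated rigidly
about a random axis; amplitude auto-tuned toward 30% acceptance during
burn-in), single-base twists about the sugar, and small single-bead
displacements.  The displacement move matters: pivots preserve every bond
length exactly, so without it the harmonic terms would never thermalize
and distorted geometries could never relax.  Energies are maintained
incrementally (cross-terms only for the pairwise sums; short-ranged and
O(N) terms re-evaluated in full) and are contractually equal to a
from-scratch evaluation; a periodic internal spot-check asserts this
during every long run.  Proposals that drive two phosphates within about
1 A are auto-rejected as deep excluded-volume violations.

Replica exchange uses 10 rungs at 25-110 C by default (25, 31, 37, 45,
54, 64, 74, 86, 98, 110).  Because the potential is temperature-dependent,
the exchange exponent is the generalized four-term form

    Delta = bj E(xi,Tj) + bi E(xj,Ti) - bi E(xi,Ti) - bj E(xj,Tj),

which preserves detailed balance for T-dependent potentials.  The printed
source expression carries an inconsistent beta index on its last term;
the detailed-balance-consistent form above is implemented.  Cross-rung
energies rescale the neutralization pattern by the ratio of condensation
baselines at the two temperatures (an exact re-solve is a flag).
Exchanges alternate even/odd rung pairs on a fixed sweep stride.
Trajectories are deterministic for a fixed seed in single-worker mode;
each replica owns an independent seeded generator and exchanges swap
conformations, not streams.  (Multi-worker execution is accepted in the
configuration but runs serially; parallel workers are future work.)

## Model selection and refinement

From the coldest replica the 1000 lowest-energy coordinate frames are
clustered by iterative largest-cluster extraction at a threshold of
0.1 A per nucleotide (5 A for a 50-mer): repeatedly take the structure
with the most neighbours within the threshold, remove it and its
neighbours as a cluster, until the pool is exhausted.  The medoids of the
three largest clusters are reported, the largest-cluster medoid ranked
first, followed by the single lowest-energy decoy (a flag promotes the
lowest-energy decoy to the top instead).

Refinement is room-temperature MC with the helix bonded set on paired
residues, bracketed by downhill-only quench sweeps (before, to settle the
input's basin; after, from the best state seen), returning the best-energy
conformation.  Moves that would lose any base pair present on entry are
rejected, implementing the pairing-preserved-or-improved contract.  Note
what this does and does not do: a coherently deformed helix (over-twisted,
stretched, pairs intact) relaxes monotonically back toward the canonical
geometry, but uncorrelated white-noise perturbations large enough to break
pair detection leave the walker without a restoring force toward the
original pairing (undetected pairs contribute no energy), and the flat
soft modes of a short duplex allow thermal samples 1-3 A from the
minimum.  Refinement regularizes stems; it is not a global optimizer.

## Thermal analysis

Conformations are classified by stem retention: stems are maximal runs of
stacked pairs in the folded secondary structure (runs shorter than 2
dropped by default); a stem counts as retained when at least half of its
pairs are present; the label is the retained subset (2^k states for k
stems: F, U and intermediates named `Im<kept>` internally, renamed to the
fraction-ranked prime convention I1, I1', ... at report time).

WHAM combines the (state, energy-bin) histograms of all replicas: 100
equal-width energy bins spanning the pooled energies with the extreme
values at the first/last bin centres, bias factors
`exp[(beta_target - beta_i) E_k]` at bin centres (energies shifted by the
pooled mean for overflow safety; the shift cancels exactly), fixed-point
iteration to `max |Delta ln Z| < 1e-8` at every target temperature.
Recorded total energies at the sampling temperature are used as-is; the
temperature dependence of the potential therefore biases the reweighting
slightly, mitigated by the coarse state space and the two-state fits.

Folded and unfolded fractions are fitted by least squares to

    fF(T) = 1/(1 + exp((T - Tm1)/dT1)),
    fU(T) = 1 - 1/(1 + exp((T - Tm2)/dT2)),

with Tm the 0.5-crossing; fits outside the simulated span attach an
extrapolation warning, and constant curves are rejected (which is how the
degenerate empty redefined-folded subset fails).  `redefine_folded`
relabels states retaining a chosen stem subset as folded before fitting,
for comparison with experiments that melt multiple stems cooperatively.
The dominant unfolding pathway is the deduplicated sequence of
maximal-fraction states from cold to hot; only fraction trajectories are
reported (no flux decomposition).

## All-atom reconstruction

Each unpaired nucleotide (or Watson-Crick pair, as one unit) is replaced
by the library template whose CG anchors (P, C4', N1/N9 per residue)
superpose onto the target beads with minimal RMSD; the bundled library is
synthetic — idealized fragments generated from the package's parametric
duplex geometry, with planar polygonal base rings and backbone atoms at
idealized internal coordinates, five variants per key differing in the
5'-tail tilt (which changes the anchor triangle, so template selection is
well posed and every template's own CG projection rebuilds it exactly).
O3' is placed toward the ideal next phosphate, so seams in helical
regions land at 1.6 A; loop-region seams drift and inter-unit clashes are
flagged per residue rather than resolved (external all-atom refinement is
deliberately out of scope).  Users can build libraries from curated PDB
files (`fragments_from_pdb` + `build_library`, greedy max-min diversity
selection).

## Synthetic validation fixtures

* `wham_twolevel` — replicas holding exact Boltzmann proportions of two
  microstates (deterministic rounded counts), so WHAM output has a closed
  form; it validates the estimator, not sampling noise.
* `planted_decoys` — widely separated rigid families with 0.3 A jitter;
  validates clustering bookkeeping, not borderline cluster splitting.
* The 12-nt hairpin (`GCGCTTTTGCGC`, four G:C pairs, T4 loop) is the
  reduced-scale folding system: large enough to have a real
  folded/unfolded transition, small enough for minutes-scale runs.
* Deterministic self-avoiding coils from the loop equilibria seed folding
  runs and serve as geometric null models.

None of these reproduce real-data features such as non-canonical pairs,
sequence-dependent flexibility beyond dimer stacking, or explicit-ion
effects; passing tests demonstrate internal consistency of the estimators
and samplers at reduced scale, not benchmark-grade accuracy on
experimental structures.

## Problem sizes and numerical choices

The shipped validation and acceptance computations use desk-scale sizes
chosen as the smallest systems that exhibit the phenomenon: 5-12 nt
chains, 2-3 replica rungs, a few thousand sweeps — a full multi-way
junction production run (38-53 nt, 10 rungs, 10^5+ sweeps) uses the same
code paths unchanged.  Degenerate geometry is handled by clamping cosines
to [-1, 1] in angles, capping pair distances away from zero in pairwise
kernels, and rejecting proposals with near-coincident phosphates.
Bonded terms never span a recorded chain break (breaks model strand
ends), and the minimum pairing separation of three intervening residues
applies only within an unbroken strand, which is how two-strand duplex
fixtures are represented under a single residue numbering.

## Known limitations

* Only canonical A-T/G-C pairs; no G-T wobbles, triplexes or quadruplexes.
* Implicit ions cannot overcharge; very high multivalent concentrations
  are outside the model.
* The softmax charge redistribution preserves the chain-average
  neutralization by construction, so differences in mean f between
  folded and unfolded ensembles arise only through clamping and blending,
  not through the spatial term itself.
* Single-scale depth calibration against one hairpin; absolute Tm for
  arbitrary motifs should be treated as semi-quantitative.
* Serial execution only; long production runs are CPU-hours.
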