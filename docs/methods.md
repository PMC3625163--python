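# Methods

## The problem

A protein sequence must both fold and function, and the two demands compete:
binding sites are conserved for chemistry, not for folding. One way to ask
how much function costs in folding terms is to remove it structurally: take
a set of proteins that share a fold but have unrelated functions, extract
the backbone and contacts they share — the *folding motif* (FM), a
"function-less" consensus scaffold of the fold — and compare its folding to
that of the wild-type members. `foldmotif` implements that construction and
the coarse-grained folding analysis around it: structure-based (Gō) models,
bias-enhanced Langevin sampling near the folding temperature, free-energy
profiles and folding-route analysis along the fraction of native contacts.

## Folding-motif construction

Given a multiple structural alignment of K members (imported from an
external structural aligner, or computed by the builtin progressive
aligner — a convenience with no claim of parity with STAMP-class tools):

1. **Positions.** An alignment column becomes an FM position when strictly
   more than an occupancy fraction (default 50%) of the members hold a
   residue there; for K = 13 that means 7 or more. The occupancy curve
   (positions surviving at support ≥ k, k = 1..K) shows how sensitive the
   FM length is to this cutoff; a flat curve around the implied k means it
   is not.
2. **Backbone.** The raw FM coordinate of a position is the arithmetic mean
   of the superposed member C-α coordinates over non-gap members.
3. **Contacts.** An FM contact joins two FM positions whose aligned
   residues are in native contact in at least a support threshold of
   members. The threshold is chosen so that the FM packing fraction
   (contacts per residue) brackets the member median; `choose_support_
   threshold` ranks candidates by that distance and marks the bracketing
   pair.
4. **Adjacency check.** Every consecutive FM pair must be backbone-bonded
   in at least one member; violations are reported (an optional repair that
   grafts the shortest member backbone across the gap is out of scope —
   violations are reported, not repaired).
5. **Relaxation.** Mean coordinates do not respect virtual C-α bond
   geometry. The raw backbone is relaxed under a stiffened SBM whose bond
   targets are all reset to 3.8 Å and whose dihedral and contact constants
   are raised to the angle constant (K_φ1 = ε1 = ε2 = 20, K_φ3 = 10),
   so bonds snap to the canonical length while angles, dihedrals and
   contacts hold the raw geometry: loops move, the core stays put. The
   schedule — Langevin at k_BT = 0.2 ε, 5×10⁴ steps of 5×10⁻⁴ reduced time
   units, then an L-BFGS polish, then a rigid-body re-fit onto the raw
   backbone — is a numerical choice; only the outcome (bond distribution
   sharply peaked at 3.8 Å, small core displacement) matters. FM contact
   lengths σ_ij are measured on the relaxed FM backbone, so the simulated
   model is internally consistent with its own native state.

Contact maps default to: any heavy-atom pair within 4.5 Å, sequence
separation |i−j| ≥ 3, σ_ij = native C-α distance. The criterion is
pluggable and contact lists can be imported verbatim from TSV, because
published counts depend on the atomic-contact tool that produced them.

## The C-α structure-based model

One bead per residue at the C-α position:

V = Σ K_r (r−r0)² + Σ K_θ (θ−θ0)² + Σ [K_φ1(1−cos(φ−φ0)) + K_φ3(1−cos 3(φ−φ0))]
  + Σ_contacts ε1 [5(σij/r)¹² − 6(σij/r)¹⁰] + Σ_non-contacts ε2 (σ/r)¹²

with K_r = 100, K_θ = 20, K_φ1 = 1, K_φ3 = 0.5, ε1 = ε2 = 1 in units of the
base scale ε (1 kcal/mol), and σ = 4.0 Å for the excluded-volume term.
r0, θ0, φ0, σij are measured from the native structure, so the folded state
minimises every term. Non-native pairs interact only repulsively. Pairs
with |i−j| < 3 are excluded from the repulsion (their geometry is governed
by the bonded terms; at the native virtual-bond length 3.8 Å < σ they would
otherwise strain the native state). Internally everything is in reduced
units — length Å, energy ε, mass 1, k_B = 1, time √(mÅ²/ε) — so scaling the
physical ε rescales reported energies and temperatures without touching a
single trajectory; T_f is exactly linear in ε by construction, and the
linearity test is a check that the implementation respects it.

Forces are analytic (the dihedral gradient follows the standard
four-point construction and is validated against central differences to
10⁻⁵ relative); an independent scalar-loop evaluator of the same potential
exists purely as a cross-check of the compiled kernel.

## Sampling

Dynamics is BAOAB-split Langevin, default friction 1 (reduced), timestep
5×10⁻⁴; friction 0 degenerates to velocity Verlet and conserves energy to
~10⁻⁴ ε per 10⁴ steps on desk-scale systems. Identical configuration and
seed reproduce a trajectory bit for bit.

The folding reaction coordinate is Q, the fraction of native contacts with
r < 1.2 σij (community standard for C-α models). Q is discrete — multiples
of 1/m for m contacts — and free-energy profiles are binned with one level
per bin (`natural_q_bins`); binning m+1 levels into an unrelated number of
bins superimposes a ±ln 2 sawtooth on F(Q) large enough to corrupt basin
and barrier detection.

When barrier crossings near T_f are rare, the transition region can be
sampled under a Gaussian-well bias W(cv) = −A·exp(−(cv−c)²/2w²) on either the total
potential energy (in which case the MD force is the native force rescaled
by 1 + dW/dE) or on a smooth differentiable Q (logistic contact indicators,
softness 0.2 Å). W is stored per frame and removed exactly by importance
reweighting; runs at different temperatures and biases are combined with
self-consistent WHAM weights, with every run's bias evaluated on every
frame from the stored energy and smooth Q. Temperature reweighting uses the
stored unbiased energies and is trusted only near the run temperature (the
effective sample size collapses quickly; below 50 a warning is recorded).

`estimate_tf` locates the folding temperature as the T at which the folded
(Q above the barrier top) and unfolded ensembles carry equal weight.  Its
protocol: short native-start scans bracket the melting region; a fixed
ladder of longer native-start runs (default six runs of 2×10⁶ steps at
timestep 10⁻³, covering the bracket padded below and above) is pooled
with WHAM, and the ladder is extended a bounded number of times when it
turns out to sit entirely on one side of the transition — short scans are
hysteretic and cannot be trusted to place the bracket; the
pooled profile is scanned over temperature for the most prominent pair of
basins whose minor side carries at least 5% of the weight (tiny reweighted
tails can shape −ln p into convincing-looking wells, so population
matters, not just shape); the barrier top of that profile is frozen as the
folded/unfolded split (falling through ranked candidates when a phantom
split fails to bracket the balance) and the pooled folded population — a
smooth, monotone function of temperature — is bisected for ½; one
refinement run at the estimate sharpens the statistics where the profile
is reported, whose basins are then anchored as the per-side minima of the
established split.  A Gaussian-well
bias can be supplied and is handled exactly by the WHAM weights; the
default is unbiased, because desk-scale folders cross their barriers
unassisted many times per ladder run, whereas bootstrapping a useful
energy-well bias requires the barrier estimate the bias is meant to
obtain.  Because the estimate works entirely in reduced units, rescaling
the physical ε leaves every trajectory untouched and T_f in kcal/mol
scales exactly linearly — the linearity check probes that covariance end
to end.

## Landscape analysis

F(Q) = −ln of the weighted Q histogram, shifted to zero at its minimum and
expressed in k_BT of the target temperature — at T_f, the scaled barrier
ΔG‡/k_BT_f whose changes order folding rates across models. Basin detection
is topographic: among local minima of the lightly smoothed profile at least
0.2 apart in Q, the pair with the most prominent intervening barrier wins;
this is robust both to noise dimples inside one broad basin and to profiles
tilted away from T_f. The barrier is quoted from the unfolded (lower-Q)
basin; at T_f the basins are equal and the choice is immaterial. Barrier
differences below ~2 k_BT — the roughness of the folding funnel — are
reported as residual, not significant.

Route maps give each contact's weighted formation probability inside a
narrow Q window (half-width 0.025 by default, grid 0.05…0.95 in steps of
0.05); backtracking is a contact whose formation probability drops by more
than 0.25 between some pair of windows Q1 < Q2, reported with its maximal
drop and interval.

## Synthetic study systems

The generators produce the study conditions; they are fixed, not tuned per
experiment.

* `make_ideal_fold` builds idealized self-avoiding C-α chains (hairpin,
  helix-like, compact-random) with exact 3.8 Å virtual bonds; strands
  zig-zag out of plane (±0.5 Å) so no angle triple is collinear. Hairpin
  contacts pair (i, n−1−i) across the strands at loop separations ≥ 6 —
  five contacts for n = 16 — with the two tightest turn pairs left to the
  bonded terms.
* `make_family` decorates a template core into a structural family: 13
  members by default, decoy bulge loops inserted at two sites in at most 6
  members each (so the >50% rule must reject them), isotropic 0.3 Å
  coordinate noise, optional core deletions (never adjacent, never
  terminal), and a random rigid pose per member. The ground-truth alignment
  (pre-pose coordinates and column labels) is returned, which is what makes
  recovery testable: selection at 50% must return exactly the core columns.
  What this emulates: loop decorations, noise and indels around a conserved
  core. What it does not: genuine structural divergence of the core,
  aligner errors, sequence-dependent contact variation — so a perfect
  recovery here bounds pipeline correctness, not real-data performance.
* `make_toy_twostate` builds the ~30-bead folder used wherever a full-size
  protein would cost hours: see below.

## The toy two-state folder

Reproducing a two-state landscape at 30 beads under this force field is
much harder than it sounds, and the design space was mapped with roughly
10⁹ steps of unbiased ground-truth trajectories before freezing the
generator:

* Designs in which every pairing step is immediately rewarded — plain
  hairpins, three-strand meanders, four-strand closed barrels at several
  contact densities — melt *continuously*: their basin slides with
  temperature and no barrier above ~0.5 k_BT survives at the balance
  point.
* Designs in which all reward is deferred to the distal rungs of a long
  hairpin have a genuine multi-k_BT loop-closure barrier, but crossing it
  from a fully disordered coil takes far longer than any desk-scale run:
  under this potential the denatured chain's dihedral barriers
  (≈1.5 ε per joint) and the near-straight native strand geometry make
  global reconfiguration of a 30-bead coil a ≳10⁷-step process, so
  folded-start and extended-start simulations never reconcile and any
  "equilibrium" read from either alone is a hysteresis artifact.

The shipped design threads this needle: a two-strand hairpin whose
contacts come in two sequence-separation bands.  A near-turn band
(separations 3–6) stays formed in the compact denatured state and anchors
the strands; a distal band (separations ≥ 18) forms only in the full
hairpin; the rungs between carry no contacts.  Crossing from the anchored
denatured state to the folded state requires ordering the unrewarded
stretch — a barrier of ≈1–2 k_BT_f crossed by *local* zippering, hundreds
of times per ladder run.  Its profile at T_f shows an unfolded basin near
Q ≈ 0.2 (the near band), a folded basin near Q ≈ 0.55–0.75, and a single
intervening barrier.

Two properties of this toy differ from the idealized picture of deep
symmetric wells and must be kept in mind when reading the validation
numbers.  First, the *sampled denatured ensemble is the compact
disordered state connected to the folded one by observed transitions*;
fully extended coils exchange with it on timescales far beyond the
protocol's runs (verified directly: extended-start simulations of 10⁷
steps never form a single contact) and are therefore not part of the
reported equilibrium.  Second, the two basins have unequal widths — the
folded side is a broad plateau — so at the population-balanced T_f the
basin *minima* differ by about +1 k_BT (folded shallower); population
balance and depth equality coincide only for width-symmetric landscapes.
Both facts are properties of this Hamiltonian at this chain length, not
of the analysis machinery, and the validation battery reports the
measured gap rather than forcing it.

## Problem sizes

Desk-scale validation uses the 16-bead hairpin (oracles), the 2-bead
spring (thermostat statistics, four 10⁶-step runs), a 1-D double well with
a 6 k_BT barrier (reweighting against quadrature), the 13-member synthetic
family (FM recovery) and the 30-bead toy folder (folding temperature,
landscape, routes; each T_f estimate runs a six-rung ladder of 2×10⁶-step
simulations plus one refinement run at the estimate, roughly two minutes
of single-core time). Full-size runs on the 13 β-trefoil chains require
downloading the deposited structures and importing an external alignment
and contact lists; the machinery is the same, only the inputs grow.

## Known limitations

* The builtin aligner is a star alignment with iterative monotone
  correspondence; it recovers rigid motions and isolated indels but is not
  a substitute for a reference structural aligner on divergent families.
* Published per-protein contact counts depend on the atomic-contact tool
  that generated them; the built-in 4.5 Å heavy-atom criterion will not
  reproduce them exactly — import the original lists to do that.
* Temperature reweighting is local; the T_f search spends most of its
  budget re-running rather than extrapolating far.
* Route maps require coordinate-saving runs; memory grows linearly with
  saved frames.
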