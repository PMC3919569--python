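# Methods

`nucleoidmc` simulates the *E. coli* chromosome as one or more self-avoiding
worm-like chains confined to the nucleoid, and measures how well the
chromosome copies segregate under different combinations of constraints:
macrodomain (MD) condensation and forced localization of the origin and
terminus of replication. This note records the model, the numerical choices
and their rationale, and what the desk-scale runs do and do not show.

## Chain model

A chromosome of `G` base pairs is a closed (or, for replication pieces,
open) chain of `N` rigid cylinders:

* linear density 100 bp/nm along the fiber, so the contour length is
  `G / 100` nm;
* three cylinders per persistence length, segment length `ls = 100/3` nm;
  the default 4.64-Mb genome gives `N = 1392`;
* hard-core fiber diameter 35 nm by default (25–50 nm supported): two
  segments may not approach closer than the fiber diameter
  (self-avoidance);
* bending energy `E = κ Σ_joints (1 − cos θ)` in units of kBT (T = 310 K).

**Discretization correction for the bending constant.** The naive discrete
Kratky–Porod choice `κ = lp/ls = 3` produces a chain whose tangent
correlation decays with an *effective* persistence length
`−ls / ln(coth κ − 1/κ) ≈ 84 nm`, not the intended 100 nm — at three
cylinders per persistence length the continuum identification is 16% off.
We therefore calibrate `κ` so that the discrete chain reproduces the target
persistence length exactly: `⟨cos θ⟩ = coth κ − 1/κ = e^{−ls/lp}`, giving
`κ ≈ 3.505` for the standard discretization. This is a property of the
model definition (the persistence length is the physical input), not a fit
to any observable; with it, the unconfined 4.64-Mb ring equilibrates at a
gyration radius ≈ 3.0 × the 400-nm nucleoid radius.

**Overlap exclusions.** Because `ls < d` (33.3 vs 35 nm), next-nearest
segments of a perfectly straight chain lie closer than the hard core by
construction. The overlap test therefore skips segment pairs that share a
vertex *or* whose endpoint sets are joined by a single bond (this includes
pairs meeting across a junction). The remaining pairs implement
impenetrability; the main physical consequence of the extended exclusion is
that hairpins of radius below ~17 nm are not additionally penalized, which
at `κ ≈ 3.5` are vanishingly rare anyway.

## Replication-stage topologies

* **G1** — a single circular chain.
* **S** (half-replicated) — three linear pieces sharing two replication-fork
  vertices: the unreplicated piece (Right + Ter + Left regions) and two
  replicated copies (NS-left + Ori + NS-right each). Forks sit at the
  ori-proximal borders of the Right and Left macrodomains, which places the
  replicated fraction at 2.24/4.64 of the genome.
* **G2** — two circular chains sharing their terminus (dif) vertex; a
  dissociated-termini variant is available.

Junctions are implemented as literally shared vertex coordinates (merged
vertices), so the binding constraint can never be violated.

## Constraints and energies

* **Nucleoid** — a right cylinder along x with flat caps, radius 400 nm,
  length 1.8–2.0 µm (G1), 2.6–3.0 µm (S), 3.6 µm (G2). Breaching it is a
  hard rejection. "Longitudinal position" always means x.
* **Macrodomain condensation** — the members of a condensed region must
  stay within a sphere of diameter 360 nm (hard constraint), and an
  optional harmonic bias `½ k Σ |r_i − c|²` with `k = 2×10⁻⁴ kBT/nm²`
  pulls them toward the sphere center; `k = 0` gives a pure hard-sphere
  mode. `k` is chosen so the bias alone confines members to an rms radius
  `√(3/k) ≈ 120 nm`, just inside the 180-nm hard radius.
* **Sphere center rule** — by default the center `c` is the instantaneous
  center of mass of the member vertices. The genomically central monomer
  is available as an alternative rule and is always the reference point
  for the localization statistics (ρ, λ). The central-monomer rule cannot
  be used as the *constraint* center for bound-termini topologies: the
  central monomer of both Ter copies in G2 is the shared junction vertex,
  which would force the two Ter spheres to be exactly concentric — at the
  intra-MD density implied by the standard parameters (φ ≈ 0.31 per
  sphere) a concentric pair is geometrically impossible, and at reduced
  density it creates artificial Ter–Ter mixing. With the center-of-mass
  rule the two spheres share the junction at their interface and sit side
  by side, as observed for the paired ter foci in vivo.
* **Pins** — a locus is tethered by `½ k (x − x₀)²` with
  `k = 1.2×10⁻³ kBT/nm²` (~30 nm rms) to a target *class*: mid-cell/septum
  (x = 0), quarters (±L/4), pole (±(L/2 − R)). Class targets act on the
  longitudinal coordinate only, because the imaging that motivates them
  constrains only longitudinal positions; explicit 3D point targets are
  also supported. Pin spring constants are model choices (the original
  values are not published); both are configuration keys.

## Monte-Carlo sampling

The time unit is the **sweep**: one proposed update of one randomly drawn
block of contiguous cylinders. Moves preserve bond lengths exactly:

* **crankshaft** — rigid rotation of a block about the axis through its two
  anchor vertices, angle uniform in [−a, +a]. If the block interior
  contains a junction, the chains hanging off that junction are co-rotated
  rigidly (the rotation is an isometry fixing the anchors, so every bond
  is preserved). Block length is uniform in [1, max_block]; max_block
  defaults to 50 segments.
* **end rotation** for free-ended linear chains; **junction reflection** —
  a degree-3 fork vertex is reflected through the plane of its three
  neighbors (the only other solution of its three bond constraints);
  optional rigid **component translations** for free/phantom test systems.

Proposals are symmetric; acceptance follows Metropolis on ΔE/kBT with hard
rejection of overlap, confinement or sphere breaches. The rotation
amplitude adapts toward a 30–50% acceptance rate during equilibration only
and is frozen during measurement, so detailed balance holds over every
sampled stretch. One MT19937 stream drives a run; given the seed, runs are
bit-reproducible. Overlap detection uses a linked-cell grid over segment
midpoints (cell ≥ segment length + hard core, 27-cell neighborhoods);
because every move is an isometry of the moved set, only moved–static
pairs and anchor-straddling segments are re-tested. Unconfined systems are
recentered between chunks (a pure translation) so the collision grid stays
finite.

**Blocks must be able to carry a macrodomain.** A condensed MD can only
translate when an entire sphere's membership fits inside one block; with
blocks capped below the member count, MDs are frozen in place. Production
runs with condensed MDs therefore set max_block above the largest MD
membership (100 segments for the desk-scale systems, whose MDs hold ~80
segments; 350 for the full-size single-MD experiment, whose sphere holds
240).

## Initialization and annealing

Initial states are exact-bond-length layouts: a regular polygon for a ring,
two externally tangent polygons in *perpendicular planes* for the G2 dimer
(coplanar tangent rings systematically wind their ter-proximal arcs around
each other and later lock during condensation), and three circle arcs
through the two fork vertices, in planes 120° apart, for the S topology.

These layouts are far more extended than the nucleoid, so each run anneals
into its constraints, mirroring the published initialization (equilibrate
with all forces in a large volume, then slowly reduce the volume):

1. **Condensation** (condense-then-confine default): MD sphere radii start
   at the current member extent and shrink by 2% per stage
   (`sweeps_per_stage` sweeps each). During shrinking the sphere walls are
   *soft* (harmonic in the excess distance, `k_wall = 10⁻³`), so loops that
   protrude can fluctuate outward and unthread instead of locking. Once
   radii reach their targets, `k_wall` ramps 10⁻³ → 1 kBT/nm², squeezing in
   the members that equilibrium pressure holds just outside. If a large
   excess survives the ramp (a trapped loop), the affected spheres are
   re-expanded by 1.6× and the cycle restarts (up to 4 cycles) before the
   run aborts with an "annealing stalled" error.
2. **Confinement**: the cylinder shrinks the same way — soft walls while
   shrinking, stiffness ramp, then hard walls. A confine-then-condense
   schedule (volume first, spheres second) implements the alternative
   "increasing density" protocol.
3. Once every wall is hard and satisfied, hard constraints hold in every
   subsequent state; all measurement happens after an additional
   equilibration stretch.

The piston rule — a vertex already beyond a hard boundary may move but
never farther out — is exactly the plain hard wall for feasible states and
only exists so that annealing can absorb sub-nanometer residues; sampled
states are always strictly feasible (audited per frame in the tests).

## Segregation statistics

* **Slice histograms**: monomer counts in 200-nm slices along x, normalized
  per chromosome; a final partial slice is its own bin. A junction vertex
  is counted once, for the lower-numbered chain.
* **Unmixing parameter** `μ = ½ Σ_i |h₁(s_i) − h₂(s_i)|`: the
  total-variation distance between two chromosomes' slice histograms —
  0 for perfectly mixed, 1 for disjoint. In S phase μ is computed for all
  three chain pairs; figures of merit quote the replicated–replicated pair
  unless stated. Summaries report the mean and the 10–90% quantile band of
  the per-frame distribution.
* **Polar occupancy** ρ: fraction of frames in which the MD's central
  monomer sits beyond the cell quarters (|x| > L/4); ρ₀ is the same
  quantity for the fiber-diameter control, i.e. the bare chromosome
  tracking the same locus. **Localization parameter**
  `λ = (ρ − ρ₀)/(1 − ρ₀)`: 0 = no positional preference, 1 = always polar.
* **Patterns**: tracked loci (region centers) are ordered by x; the label
  sequence is mirror-canonicalized (the lexicographically smaller of the
  sequence and its reverse), so reflected conformations map to one
  pattern class. Frequencies are reported per canonical class.

## Desk-scale experiment conditions

The published runs use N = 1392 per chromosome and 10⁹–2×10⁹ sweeps. The
package's reproduction experiments (`nucleoidmc.reproduce`, also behind
`scripts/acceptance.py` and the `nucleoidmc reproduce` command) rerun the
same measurements at sizes a single CPU handles in minutes:

* the unconfined gyration-radius measurement runs at full size (N = 1392,
  150 frames after large-block equilibration from the polygon start);
* the single-MD localization experiment also runs at full size (N = 1392,
  2-µm nucleoid, 400-nm sphere): the polar push on a condensed MD is an
  osmotic effect of the surrounding chain and vanishes if the chain is
  diluted, so it cannot be measured on a reduced chain in the full-size
  nucleoid (measured there: λ ≈ 0.04). Blocks of up to 350 segments let
  the 240-member sphere translate as a unit (0.8×10⁶ equilibration +
  1.8×10⁶ sampling sweeps, 2000 frames); the ball localizes stably at a
  pole (ρ ≈ 1), which makes λ insensitive to ρ₀. The fiber-diameter
  control is the bare ring; since every monomer of the homogeneous ring
  is statistically equivalent to the tracked locus, ρ₀ is averaged over
  all monomers, which converges in a much shorter run;
* the segregation (μ) experiments scale the genome to one third (N = 464
  per chromosome copy) inside the full-size nucleoid, keeping the
  discretization, fiber diameter, region mass fractions, pin targets and
  slice thickness unchanged;
* MD spheres in the multi-MD segregation experiments scale as
  `360 nm × (1/3)^{1/3} ≈ 250 nm`, preserving the intra-MD volume fraction
  (φ ≈ 0.31) — the quantity that makes condensed MDs behave as effectively
  impenetrable balls, which is the mechanism under test;
* each μ condition runs 2 independent replicates (3 for the strongly
  metastable bare-G2 pair) of 2–3×10⁶ sampling sweeps after 0.8–2×10⁶
  equilibration sweeps, a frame every 5×10³ sweeps; the pooled μ
  distribution is summarized by its mean and 10–90% quantile band, with
  per-replicate means reported and inconsistent pairs flagged per the
  published two-simulation rule.

What the scaled runs show: the *relative* segregation behavior of the
constraint combinations (bare vs condensed vs pinned), the polar
localization of large condensed MDs, and the printed μ levels for the
strongly-constrained states, which are set by region mass fractions and
pin geometry more than by absolute chain length. What they cannot show:
absolute time scales, the weak-confinement corrections that depend on
total chain length (scaled-down homogeneous systems demix somewhat more
easily than full-scale ones), or leading/lagging-strand asymmetries (the
strands are indistinguishable in this model).

## Known limitations

* No explicit supercoiling, twist, nucleoid-associated proteins, or
  replisome bodies; replication stages are static topologies.
* The MD condensation potential is a coarse stand-in for an unknown
  mechanism; only its geometry (sphere diameter, density) is constrained
  by data.
* Junction mobility in G2 relies on whole-ring co-rotations and is slow;
  observables tied to the absolute diffusion of the terminus junction
  should not be read quantitatively.
* The synthetic initial layouts are deterministic; run-to-run variability
  comes only from the seed, and replicate pairs are compared (and flagged,
  never silently averaged) following the published two-simulation
  protocol.
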