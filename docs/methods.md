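# Methods

## The model

`mitobrush` simulates the post-prophase compaction of a mitotic chromatid
driven by condensin *bridging*.  The chromatin fiber is a bead-spring
polymer at 2 kbp per bead (bead diameter σ is the length unit, k_BT the
energy unit).  The prophase state is a **bottlebrush**: the chain is tiled
by consecutive loops, drawn independently and uniformly from 60–120 kbp,
with each loop closed by a *looping-condensin* spring joining its two root
beads.  Adjacent loops share their boundary root, so *n* loops carry
*n + 1* anchors.  Loop-extrusion dynamics are deliberately not simulated:
the loops are taken as formed before the simulated window begins.

*Bridging condensins* are separate spheres (same diameter as chromatin
beads).  After a short steric phase they become weakly attracted to every
chromatin bead and strongly attracted to loop anchors.  Because a bridge
can touch several chromatin segments at once, binding raises the local
chromatin density, which recruits further bridges — the classic
bridging-induced attraction.  No bridge–bridge attraction term exists
anywhere in the energy; bridge clusters are emergent.  Entropic repulsion
between crowded loops opposes unlimited cluster growth, so the bridges
split into separate droplets along the backbone provided their number
stays comparable to the anchor count (the `auto` stoichiometry: one bridge
per attractive anchor).

## Interactions

| pair | potential | default |
|---|---|---|
| chromatin–chromatin | soft cosine core `U = A(1 + cos(π r / r_c))`, r_c = 2^{1/6} σ | A = 4 k_BT |
| bridge–chromatin (phase 2) | truncated-shifted LJ, depth normalised to ε exactly, r_c = 1.8 σ | ε_weak = 3 k_BT |
| bridge–anchor (phase 2) | same form | ε_strong = 8 k_BT |
| bridge–anything (phase 1), bridge–bridge | WCA | 1 k_BT |
| backbone + looping springs | FENE centred on r₀ = 1 σ, diverges at \|r − r₀\| = 0.9 σ | k = 30 |
| sister centromere cross-links | harmonic | k = 10 |

The chromatin–chromatin core is *bounded*: full overlap costs `2A`, so two
strands can pass through each other at a rate `~exp(−2A)`.  This is the
topoisomerase-II dial — `A = 1 k_BT` means crossing costs about as much as
thermal noise (high enzyme activity); the default `A = 4 k_BT` makes
crossing rare.  The finitely extensible bonds guarantee that no pulling
force can make a loop slip through its spring.

Why the bridge wells are 3 / 8 k_BT: the weak well must exceed ~2 k_BT for
bridging-induced clustering to beat entropy but stay shallow enough to
remain reversible on simulated timescales; the strong well then pins
bridges to anchors without freezing all exchange.  Both are exposed in the
configuration.

## Dynamics and schedule

Underdamped Langevin dynamics (BAOAB splitting), m = 1, friction γ = 1 τ⁻¹,
dt = 0.01 τ.  One seeded generator per run draws exactly one (N, 3) normal
block per step, so trajectories are bit-reproducible.  Non-bonded forces
use a Verlet list (skin 1 σ — tree rebuilds, not the pair kernel, dominate
cost at these sizes) rebuilt from a periodic k-d tree; the
periodic box is chosen at build time large enough that the chromosome
never meets its own images, and is enlarged to the full chain contour
before pulling runs.  No cylindrical confinement of any kind is imposed —
the cylinder-like compaction must emerge from the interactions alone.

The schedule has two phases: phase 1 (default 1000 steps) with bridge
attractions off — bridges diffuse sterically around the brush — then
phase 2 with the attraction wells on.  Snapshots are written every
`snapshot_every` steps, frame 0 included.

Micromanipulation: constant equal-and-opposite forces (default 20 reduced
force units per side, shared over the beads of the first and last loop)
act along the end-to-end axis for `pull_steps` (default 20 000), then are
removed for `release_steps` (default 60 000 — elastic recoil completes
within ~10 000 steps but bridging-induced re-aggregation, which restores
the pre-pull extension, needs several-fold longer); the
centroid-to-centroid extension is recorded throughout.

## Initial geometry

The anchors are laid along a *wormlike* path — a persistent random walk
(persistence ≈ 8 anchor spacings) with a weak helical modulation — and
each loop's interior beads are placed on a near-circular arc in a plane
rotated by the golden angle from loop to loop.  A short zero-temperature
push-apart with capped displacements removes build overlaps without ever
endangering a bond.  The wormlike (rather than straight) backbone matters:
a prophase chromatid is a long *flexible* brush, and a flexible filament
is strongly acylindrical (for a random walk the two minor gyration
moments differ by a factor ≈ 2.7).  Compaction then genuinely *reduces*
the acylindricity toward the more symmetric self-assembled cylinder, which
is the signal the shape analysis tracks.

## Observables

* **Gyration tensor** eigenvalues λ1 ≥ λ2 ≥ λ3; R_g = √(λ1+λ2+λ3);
  **acylindricity** c = λ2 − λ3 (eigenvalue convention, not semi-axis
  lengths; both vanish together under cylindrical symmetry).  Length =
  extent along the major eigenvector, width = mean extent along the two
  minor ones.
* **Contact probability** P(s): fraction of intra-chain bead pairs at
  genomic separation s within 2 σ (default, recorded in output metadata),
  pooled in logarithmic s-bins, averaged over the last quarter of phase-2
  frames; the exponent is the least-squares slope of log P vs log s over
  10–100 kbp.
* **Bridge clusters**: single-linkage connected components at 1.3 σ,
  labels deterministic by lowest member index; every bridge is assigned,
  singletons included.  The companion statistic **bridge foci** counts
  only clusters of ≥ 2 *chromatin-bound* bridges (within 1.8 σ of a
  chromatin bead) — the microscopy-like condensin-puncta count, excluding
  monomers still diffusing in the box.
* **Backbone metrics**: contour length over anchors in chain order and
  straightness (end-to-end / contour).
* **Lesion gap score**: a density profile along the axis joining the
  centroids of the two flanking (still condensin-loaded) chain segments;
  the score is the chromatin linear density in the central slab between
  the bodies divided by the density in equal-width slabs on the bodies
  themselves.  ≈ 1 means no gap, ≪ 1 a clear breakage.  The generic
  :func:`density_gap_score` evaluates arbitrary axial windows (optionally
  inside a tube) and is validated on synthetic cylinders with carved
  voids.

## Scenarios and study conditions

Desk-scale defaults, chosen once: wild type at 1000 beads (2 Mbp,
~22 loops), phase 2 = 150 000 steps; comparison conditions (topoisomerase
sweep, knockouts, lesions) at 600 beads with phase 2 = 100 000 steps,
where the shape observables plateau by ~60 000 steps.  Three replicate
seeds per condition; "final" values average the last quarter of phase-2
frames, "phase-2 start" is the switch-on snapshot.  Larger systems are
reachable through the `scale` multiplier.

Knockouts re-balance the two condensin activities: condensin-I knockout
doubles the loop-length range and halves the bridge count (more looping,
less bridging → shorter, wider chromatid); condensin-II knockout is the
mirror image (0.5×, 2×; shorter loops, more bridges → longer, thinner).
The factors act on the wild-type `auto` stoichiometry and are
configurable.  Knockout phenotypes are classified on replicate means with
a ±10% dead band; the *length* signal is the anchor-backbone contour (the
chromatid axis — at desk scale the whole-cloud extent is dominated by
individual loops and does not track the axis), the *width* signal the
mean cloud extent along the two minor principal axes.

Fragile-site lesions remove the looping springs of k consecutive loops
(default 3, centred on the chain) and delete the strong bridge attraction
of anchors exclusive to those loops; chain connectivity is untouched.
Lesion runs use a 1200-bead chain so that each flank holds enough loops
to condense into a distinct body on either side of the gap.

A note on the topoisomerase direction: lowering A to 1 k_BT (easy strand
crossing, i.e. *high* topo II activity) lets the collapsing brush resolve
its entanglements and reach a more compact, more cylindrical state — the
replicate-mean final acylindricity at A = 1 is *below* the high-A default.
The low-A state also has the smaller R_g in this implementation.

## What the generator does and does not emulate

The synthetic systems encode the stated study conditions (2 kbp beads,
60–120 kbp uniform loops, bridges ≈ anchors) but are far shorter than real
chromosomes (2 Mbp vs tens of Mbp), so the self-assembled "cylinder" at
desk scale is a short, stubby object and P(s) power-law behaviour holds
over 10–100 kbp only.  Real-data features deliberately absent: sequence-
specific anchor positions, loop-extrusion kinetics, bridge
binding–unbinding kinetics, condensin–condensin attraction, nucleosome-
scale structure, and Hi-C-style experimental noise.  Passing tests
demonstrate the mechanism and its parameter dependences at desk scale,
not quantitative agreement with any experimental chromosome.

## Numerical choices and degenerate inputs

dt = 0.01 τ sits ~2× below the stability bound of the stiffest default
term (the ε_strong LJ well); a hard error is raised beyond the bound.
Bond over-extension beyond 99.9% of the FENE divergence raises an
integration error naming the step; the partial trajectory is attached to
the exception.  A truncated terminal loop shorter than the configured
minimum is allowed and flagged; a single-bead terminal loop has coincident
roots and carries no spring.  Empty bridge sets, zero-length centromere
spans and lesions of k = 0 loops are all valid no-ops.  Cluster labels and
loop ids are deterministic; all stochastic code paths consume exactly one
seeded generator.

## Known limitations

* Bridge droplet coarsening is slow; at desk scale the final state is a
  necklace of droplets rather than a single smooth cylinder, and shape
  observables retain visible frame-to-frame fluctuation (hence tail
  averaging).
* The acylindricity of a ~20-loop object is noisy in absolute terms;
  comparisons are made on replicate means.
* The pulling protocol reports centroid extension of the end loops, not a
  force-ramp stress–strain curve.
* The cytological-lesion density contrast does not resolve at desk scale:
  the lesioned coil (100–200 naked beads) is comparable in size to each
  condensed flank, the flanks are loose loop-coronas whose density barely
  exceeds the naked coil, and the two tethered bodies can fuse through
  bridge–chromatin attraction — something a full-length rigid cylinder
  cannot do.  The gap score is computed and reported, but its
  bridged-vs-bridge-free direction is unreliable below a few thousand
  beads.
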