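# Methods

## The model

`hiersim` represents a macromolecule as a tree of nested convex containers.
The leaves ("atoms") are always hard spheres — Cα positions for proteins,
phosphates for nucleic acids, or abstract beads for synthetic chains.
Interior nodes are containers of one of three kinds: spheres, tubes
(capsules: straight cylinders with hemispherical end-caps) and spheroids
(ellipsoids of rotation, prolate or oblate, never scalene).  A container
both bounds its children for collision purposes and confines them
geometrically.

The engine applies no potentials, forces or velocities.  Every change of
coordinates is a fixed-size displacement ("kick") applied by one of four
correction drivers, each capped at the residual it corrects so no single
call overshoots:

1. **bumper** — hierarchical collision detection and repulsion;
2. **keeper** — returns straying children into (or onto) their parent;
3. **bonder** — pushes bonded pairs toward their assigned lengths;
4. **linker** — like the bonder, but links break permanently beyond 50%
   extension.

All purposeful motion comes from a user driver run at the start of each
cycle.  With a null driver and a model at equilibrium, the engine does
nothing: the relaxed Hilbert-chain fixture reproduces this exactly (zero
displacement over any horizon), which the test suite asserts bitwise.

A cycle runs driver → bumper → keeper → bonder → linker → centroid
synchronisation → (periodically) axis realignment.  The order is a design
choice: driver kicks are immediately counter-balanced by steric and
containment corrections, so constraint satisfaction never outruns the
steric model.  Centroid tracking runs every cycle (cheap); inertia-based
axis realignment every 10 cycles by default (more expensive, and
orientations drift slowly).

## Geometry

Sphere and tube contacts reduce to point/segment and segment/segment
distances.  Spheroid geometry is reduced to the meridional half-plane
(radial, axial), where one ellipse with focal half-distance
c = √(major² − minor²) covers prolate and oblate bodies uniformly (for
oblate spheroids the 3-D focal ring is represented by its in-plane
points).

Two point-to-spheroid routines coexist deliberately:

* `in_egg` — the focal-sum excess, scaled by 0.7 (the raw excess is twice
  the true distance in the sphere limit; halving it and applying the
  empirical 1.4 factor gives 0.7).  Exact only in sign; used where sign
  and ordering suffice: containment decisions and the tube-axis bisection.
* `vec_to_egg` — the exact signed distance and nearest surface point, via
  a bracketed Newton iteration on the Lagrange parameter of the 2-D
  point-to-ellipse problem (the rational function is convex and
  decreasing, so Newton from the analytic left bracket converges
  monotonically).  Degenerate on-axis queries use closed forms; ties at
  the exact centre break toward the local +x direction, documented and
  deterministic.

Tube–spheroid contacts bisect the axis on the `in_egg` score with a
3-point bracket (worst end discarded each round) to a 1e-4 bracket width,
then polish the minimiser against `vec_to_egg` in a local window.

Spheroid–spheroid contacts have no closed form.  The search triangulates
each surface into 8 octant triangles from its 6 axis end-points, ranks all
64 mid-point pairs, descends the best three pairs by recursive
quad-section (edge-midpoint inner triangles, every midpoint re-projected
radially onto the surface) to depth 3, and refines with a 3×3 grid of
nine points around each winning mid-point.  The result is validated by
measuring each candidate point against the opposing surface with
`vec_to_egg`; the two distances agree to a median of ~0.03% on random
disjoint pairs (the acceptance script recomputes this figure).  For the
gap actually reported by `touch()`, the candidates are then polished by
alternating nearest-point projection — the fixed point of the validation
step — which converges to the true common normal for disjoint convex
bodies; overlapping or containing configurations are resolved by
minimising the signed distance over one surface (Nelder–Mead from two
starts), with full containment handled by a support-function formula that
is exact in the sphere limit.  The pair is evaluated in a deterministic
canonical order, so the gap is exactly symmetric under argument exchange.

## Collision model

At each family the violating sibling pairs are found — exactly (all pairs)
below 20 children, by a triple-axis interval sweep above, using each
object's largest dimension — and processed worst-first.  Before two
colliding parents are repelled, the collisions between their children are
counted (m) and corrected; the parental repulsion step is then

    boot = f·soft + (1 − f)·hard,   f = exp(−m²/100),

so grazing container contacts use the soft step and deeply engaged ones
approach the hard step ("currants in jelly").  When only one of hard/soft
is configured it is used directly.  Clashing cross-family children are
each nudged toward their own parent's centre by soft/10 (breaking
family grid-lock) before being separated — by the hard step if they are
atoms, the soft step otherwise — and the cross-family examination recurses
into clashing children's own children.  Bonded or linked pairs are never
repelled, but their interiors are still examined.  At the atomic level
only hard applies.

Collision geometry uses a per-node bump radius that may differ from the
container's (keeper) radius.  For the Hilbert test chains this resolves a
real tension: a space-filling curve places sibling containers that are
spatially adjacent but distant along the chain in permanent contact, so no
single radius can both bound the leaves (needed for completeness of the
hierarchical pass) and leave the packed chain at equilibrium (needed for
the fixed-point contract).  The builder therefore offers two conventions —
"enclosing" (bump volumes cover children plus the keeper margin band;
guarantees the pass acts on every atomic overlap, verified against a flat
N² scan) and "touching" (bump radii equal half the inter-container
spacing; the chain is exactly at contact and is the relaxed fixture).

## Containment

The per-level `keep` parameter sets the correction step; its sign selects
the mode: positive confines children inside spheres and spheroids but on
the surface of tubes, negative reverses the roles.  A ±10% margin band
(0.9/1.1) around the target surface suppresses action on children that are
nearly in place.  Only the child's radius normal to its symmetry axis is
subtracted from the parent's, so tube and prolate ends may protrude.
Spheroid containment decides in/out with `in_egg` on the margin-scaled
effective body and corrects along the inverse-distance-weighted
combination of the unit vectors toward the two foci.  Protein loop
children are held inside their tube only, at a tenth of the step, with no
end-cap enforcement.  Duplex basepairs skip a generation: the phosphates
(not the basepair tube) are held on the duplex tube surface, the P–P span
across the pair is refined toward its ideal, the basepair tube tracks its
phosphates, and the inter-rung torsion is refined toward the ideal
right-handed twist.

Ideal duplex constants (P–P span across a pair, rise, twist) are stored in
one editable table, with defaults from canonical A-form (RNA: 3.0 units,
0.47, 32.7°) and B-form (DNA: 2.7, 0.48, 36°) geometry in the nucleic
internal unit.  The exact values the original ideals used are not
published; these are standard textbook geometry.

## Units and molecular mapping

Proteins: 0.6 internal units ≡ 3.8 Å (one Cα–Cα bond); the atomic bump
diameter is the minimal allowed i,i+2 Cα separation, default 5.0 Å
(configurable — the published description of this radius is ambiguous
about its unit system, so the operational definition is used).
Secondary-structure tubes use rises of 1.5/3.0/0.5 Å per residue for
helix/strand/coil and preset radii (2.3/2.7/2.0 Å; the strand value is
generous to give super-helical twist room on the surface).  Helix links
(i,i+3 at 5.1 Å, i,i+4 at 6.2 Å) and strand links (i−1,i+1 at 6.7 Å) are
preset; sheet pairings are user input.  Nucleic acids: 1 internal unit ≡
one P–P backbone bond (5.9 Å A-form equivalent).

## Drivers and protocols

**Collisions.**  Two staged bodies receive a constant approach
displacement along the line of approach, offset laterally by half the
container radius.  The default approach speed is body radius/10 per cycle,
a deliberately violent collision: because every repulsion kick is capped
at the current violation, inter-penetration accumulates only while the
closing speed exceeds the soft step, and this speed places the onset of
atomic contact near soft = hard/5 for the 8+8 crash, with a fully soft
shell (soft = hard) repelling the bodies before any contact.  The crash
bodies' outer shells are padded by 20% over their minimal enclosing radius
so a protective-shell regime exists at all.  Slow motion multiplies cycle
counts by the slow factor and divides all kicks (and the approach) by it.

**Progressive constraints.**  Constraints are activated one at a time in
descending strength order; one is activated only if it currently lies
within twice its target and is discarded permanently if it ever strays
beyond that bound.  Active constraints pull their atom pair toward the
target by the level's bond step each cycle.

**Cull protocol.**  The top-k constraints (k = 50 by default) are active
from the start; stem-loop-level objects receive random displacements whose
amplitude decays linearly to zero over the run; after a containment phase
(the first 40% of cycles) one constraint is removed every 50 cycles,
drawn from those that have failed to approach their target (fractional
violation above 0.5) with probability proportional to violation, inversely
to strength, and biased (3×) against constraints within a stem-loop.
Constraints that have approached their target are never culled — culling
exists to prune inconsistent predictions, not satisfied ones.

**Scoring.**  Models are ranked by Σ strength·max(0, 1 − |d−target|/target)
over the evaluated set: monotone in per-constraint satisfaction,
strength-weighted, equal to the summed strength when every constraint is
exact and zero when every distance is at twice its target.  The exact form
is a free choice of this package.

## Synthetic test systems

The Hilbert chains (8^levels beads, eight children per container,
consecutive bonds all equal) emulate a homogeneously packed macromolecule
with uniform density and no internal structure — ideal for isolating
collision phenomenology, but unrepresentative of real proteins' packing
heterogeneity, so passing crash tests bounds only the engine's mechanics,
not biological realism.  The toy protein trace is ideal-geometry secondary
structure with simple linkers (synthetic; not a crystal structure).  The
toy RNA is a 48-nt two-stem cloverleaf; its "known structure" for
constraint-recovery tests is generated by a deterministic teacher run
(annealing into a small target sphere without constraints), which
guarantees the constraint set is simultaneously satisfiable by the same
dynamics — real correlated-mutation constraints are noisier and partly
inconsistent, which is exactly what the culling machinery is for.

Problem sizes used by the shipped checks: contact validation on 1000
random spheroid pairs; oracle agreement on 500 instances per routine;
completeness audits on 64- and 512-atom chains over 50 seeded
configurations; 8+8 crashes over 5 seeds per soft value; constraint
recovery over 20 seeds per protocol.

## Numerical choices

* Kicks are capped at the violation they correct; corrections are
  symmetric half-steps on both bodies, applied recursively to subtrees.
* Axis bisection stops at a 1e-4 bracket; quad-section depth is fixed at
  3; point-to-ellipse Newton iterates to |F| < 1e-14.
* Clash censuses ignore overlaps shallower than 1e-9 (rounding noise from
  rigid rotations of exactly-touching packings).
* Degenerate directions (coincident centres, on-axis points) break ties
  toward +x in the local frame.
* All randomness flows from one seed per run; trajectories are
  bit-reproducible for a fixed (seed, inputs, config) triple.

## Limitations

No potentials, momenta or Monte-Carlo acceptance — the method cannot be
combined with drivers that require global energetic consistency.  No
dynamic re-parenting: subunit transfer between assemblies requires
editing the tree between runs.  Scalene ellipsoids are excluded by
design.  Sheet hydrogen bonding is not detected automatically.  The
spheroid–spheroid penetration depth for heavily overlapping bodies is a
locally-optimised estimate (exact in the sphere limit); it is sign-correct
and adequate for repulsion kicks but is not a guaranteed global maximum
penetration.
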