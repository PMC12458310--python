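# Methods

## The model

`neuritesim` implements a two-dimensional coarse-grained cell: a closed ring
of plasma-membrane beads, a concentric nuclear-envelope ring, and radial actin
filaments connecting the two. Each filament's base bead is anchored by a
harmonic spring to its nearest nuclear bead; its outermost bead is an **actin
head**, the only species that adheres to the membrane. Cortical tension is
therefore represented by a single knob — the adhesion well depth U₃ — and
membrane tension by the membrane-spring constant κ₀₀. The planar geometry is
the minimal representation in which ring contours, protrusion fingers, and
the cortex-as-barrier mechanics can all be expressed; it matches the contour
view in which simulated morphologies are usually rendered.

All quantities are in reduced units: bead diameter σ (length), k_BT (energy),
drag γ (friction); time unit τ = γσ²/k_BT.

### Potential terms

| term | form | applies to |
|---|---|---|
| stretch | ½κ(r−r₀)² | membrane ring (κ₀₀), nucleus ring (κ_nuc), filaments + anchors (κ_fil) |
| bend | κ_b(1−cos(φ−φ₀)), φ = signed turning angle | rings (φ₀ = 2π/N), filaments (φ₀ = 0) |
| adhesion | Lennard-Jones, depth U₃, truncated & shifted at 2.5σ | ACTIN_HEAD ↔ MEMBRANE pairs |
| excluded volume | WCA (purely repulsive LJ, cutoff 2^{1/6}σ), strength ε_rep | all other non-excluded pairs |
| area | ½κ_A(A−A₀)²/A₀, shoelace area | membrane ring, nucleus ring |

The spontaneous-angle bending form is chosen so that the closed rings are
mechanically relaxed as built; on a straight filament (φ₀ = 0) it reduces to
the familiar κ_b(1 + cos θ) in the interior angle θ. Every rest length, the
spontaneous angles, and the target areas are taken from the as-built
geometry, so the initial state carries no bonded or area energy — only the
non-bonded tail (head–membrane adhesion at its minimum distance, plus weak
1-3 ring contacts).

Non-bonded exclusions cover 1-2 (bonded) pairs everywhere and 1-3 (angle)
pairs on filaments only. Filament 1-3 exclusion is necessary because growth
insertion makes those distances sub-σ by construction; ring 1-3 repulsion is
deliberately *kept*, because it is what gives the membrane self-volume —
without it, an adhesion well of 30 k_BT can stack several membrane beads on
top of one another.

### Default architecture

240 membrane + 80 nucleus + 20 filaments × 19 beads = 700 beads. The split
gives even angular spacing, a 3:1 membrane:nucleus perimeter ratio, and —
because 240 and 80 are multiples of 20 — an exactly C₂₀-symmetric initial
cell, which is what makes the athermal control experiment (no net membrane
drift) a sharp test rather than a tolerance judgement. Ring radii default to
r_cell = 24σ and r_nucleus = 8σ so that both rings respect the 0.5σ
minimum-spacing feasibility rule enforced by the builder. Heads sit
2^{1/6}σ inside the membrane ring — at the adhesion minimum — so the build is
not jolted at t = 0.

### Dynamics

Production dynamics are overdamped Langevin via Euler–Maruyama,

    x(t+dt) = x(t) + F dt/γ + sqrt(2 kT dt/γ) ξ,

with ξ standard normal per coordinate, drawn bead-by-bead in index order, x
before y, from a single PCG64 stream seeded by `seed`. Identical (config,
seed) is bit-reproducible. The *deterministic* displacement is capped at
0.1σ per bead per step: the truncated LJ core has local stiffness ≈456·U₃/σ²,
which at U₃ ≥ 30 exceeds the explicit-Euler stability bound for any timestep
large enough to be useful; the cap (a standard Brownian-dynamics safeguard)
engages only at forces above ~10³ k_BT/σ, two orders of magnitude beyond the
typical force scale, and leaves the noise untouched. `step_overdamped`
exposes the cap as a parameter (`numpy.inf` disables it).

The default timestep is dt = 10⁻⁴ τ. The stiffest default term is the
protrusive filament's bending (κ_b = 200): a discrete chain's bending Hessian
has eigenvalues up to ≈16 κ_b/a² ≈ 5·10³, so dt = 10⁻⁴ keeps a ~4× margin
below the stability bound, and athermal runs descend the energy monotonically
as a gradient flow should.

A velocity-Verlet NVE mode (unit bead mass) exists only to validate the force
field: on the default 700-bead cell with thermal-scale initial velocities it
conserves total energy to better than 10⁻⁴ relative over 10⁴ steps at
dt = 10⁻⁴.

Neighbor search is a Verlet pair list with 0.4σ skin over an exhaustive
O(n²) scan, rebuilt when any bead has moved more than half the skin; at
n ≈ 700 this costs microseconds per step inside the numba kernels.

### Protrusive growth

The observation this package probes is that protrusions emerge when cortical
tension drops; the driving engine itself (microtubule-rich neurite shafts in
live cells) is represented by designated **protrusive filaments** — stiffer (κ_bend_protrusive = 200 vs 20) and growth-capable.
Every `grow_interval` of simulation time, one bead is inserted at the
midpoint of the head and its inner neighbor, and both new bonds get the
filament's native segment rest length, so each insertion adds one segment of
rest contour — a deterministic polymerization ratchet. Two guards keep the
process physical: insertion is skipped while the head segment is still
compressed below its rest length (a force–velocity stall, which also prevents
unintegrable bead pile-ups at a blocked tip), and skipped if the new bead
would land within 0.1σ of a non-bonded bead.

## Morphometrics

The membrane radial profile is measured from the arithmetic-mean membrane
centroid; the baseline R₀ is its **median**, which stays put when a long
finger skews the distribution. A protrusion is a maximal circularly
contiguous arc of beads more than `delta` (default 2σ) above R₀ with at least
`min_arc` (default 2) beads — single-bead thermal spikes do not count.
Projection length is the tip excursion of the largest protrusion; persistence
is the fraction of frames in the final half of a run whose projection length
exceeds `l_min` (default 2σ). All metrics are invariant under rigid rotation
and translation.

One geometric subtlety: displacing an arc of beads outward also moves the
mean centroid slightly toward it, so an isolated 5-bead finger built from
R = 10 to 16 on a 240-gon measures ≈5.88σ rather than 6.00σ. The exactness
tests therefore use a centroid-balanced (antipodal pair) construction, for
which the length is exactly 6.0.

## Sweeps and the shipped presets

`run_sweep` runs every (U₃, κ₀₀, replicate) cell; replicate r uses seed
`root_seed + r`, the same across grid points (common random numbers). The
headline statistic per run is the time-mean projection length over the final
half of saved frames (robust to terminal fluctuation); the final-frame and
maximal values are recorded alongside, and summaries report mean ± SEM
(sample SD/√n).

Two presets ship as YAML next to the package and encode the calibrated study
conditions:

* **fig1f** (soft membrane): κ₀₀ = 10, U₃ ∈ {0.5, 1, 3, 10, 30, 50}
  (log-spaced, bracketing the printed low/high values 3 and 30),
  5 replicates, dt = 10⁻⁴, 10⁵ steps (10 τ), growth every 0.1 τ, up to 40
  insertions. Expected behavior: an interior maximum of projection length.
  At very low U₃ the tip cannot hold the membrane — it slips sideways or
  pokes through, and the protrusion is short and unstable; at intermediate U₃
  the adhered tip drags the soft membrane into a long stable finger; at high
  U₃ the whole membrane is clamped onto the cortical shell, the tip stalls
  against it, and extension is again restricted.
* **fig1e** (stiff membrane): κ₀₀ = 500, U₃ ∈ {3, 30}, 5 replicates,
  6·10⁴ steps (6 τ), up to 30 insertions. With a nearly inextensible
  membrane, finger growth requires recruiting membrane length tangentially
  past the adhesion wells of the static cortex heads. At U₃ = 3 those wells
  are thermally passable and dynamic protrusions appear quickly; at U₃ = 30
  they are not, and the protrusion creeps far more slowly. The contrast is
  kinetic: run several times longer, even the strongly adhered tip eventually
  crosses the persistence threshold. The preset run length captures the
  regime in which low cortical tension *facilitates dynamic protrusion*.

Run lengths, growth rates, and the protrusive bending stiffness were fixed by
calibration runs against these two qualitative properties (checked across ten
independent root seeds) and then frozen in the preset files. The protrusive
engine stiffness is a per-condition constant: against the ~50× stiffer fig1e
membrane a κ_b = 500 engine is needed for low-adhesion protrusion to occur
reliably within the simulated window (with κ_b = 200 roughly a third of root
seeds show no contrast), whereas in fig1f the same stiff engine punches
through the high-U₃ cortical clamp and erases the interior maximum, so fig1f
uses κ_b = 200. Each preset's comparison (low vs high U₃) is internal to one
engine, so the asymmetry does not enter any contrast being measured.

## What the synthetic cell does and does not capture

The generator produces the full study system — there is no external data.
It captures: a contractile-shell membrane with excluded volume, a
cortex-as-adhesion layer whose strength is tunable in k_BT, an
incompressible-ish cytoplasm (area constraint), and a load-stalling
polymerization engine. It does **not** capture: three-dimensional membrane
mechanics, actin turnover or myosin contractility as processes, filament
severing/branching, hydrodynamic coupling, or adhesion to a substrate.
Passing sweeps therefore demonstrate that the *mechanical barrier* logic —
adhesion-mediated cortical clamping vs polymerization pushing — reproduces
the observed phase behavior in a minimal setting; they are not evidence
about biochemical mechanism.

## Numerical choices and degenerate inputs

* Tolerances: force–gradient agreement 10⁻⁶ relative (central differences,
  h = 10⁻⁶); energy-breakdown closure 10⁻¹² relative; athermal descent
  monotone to 10⁻⁹ per step.
* Builder rejects rings with bead spacing < 0.5σ, naming the offending ring,
  and configs violating their invariants (counts, radii ordering, positivity).
* `validate_cell` reports (never raises) duplicate bonds, out-of-range
  indices, non-finite coordinates, coincident bonded beads, broken ring
  closure.
* Overlapping non-bonded beads (r < 10⁻⁶σ) abort a run naming the pair;
  non-finite displacements abort naming the step.
* Ties in protrusion detection: arcs are scanned from the first sub-threshold
  bead, so records are unique and disjoint; the tip is the first
  maximal-excursion bead of the arc.
* Angle forces guard the degenerate collinear-with-zero-length case
  (|a||b| = 0) by skipping the triple; bonded beads at identical positions
  are a validation error upstream.

## Known limitations

* At U₃ ≳ 30 the adhesion wells are deep enough that membrane beads
  occasionally hop between wells only on long timescales; persistence
  estimates at stiff membranes consequently carry large seed-to-seed
  variance (SEM ≈ 0.15 with 5 replicates).
* The displacement cap biases trajectories in the rare extreme-force events
  it clips; it is a stability device, not an integrator improvement, and NVE
  validation runs never engage it.
* Growth is deterministic and insertion-based; retraction, catastrophe, and
  stochastic polymerization kinetics are out of scope.
* Metrics assume the membrane ring remains a simple (non-self-intersecting)
  polygon; heavily blebbing low-U₃/low-κ₀₀ cells can transiently violate
  this, in which case circularity may exceed 1 by small amounts.
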