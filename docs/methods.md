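# Model and methods

## The physical model

`condensac` simulates the compaction of a mitotic chromosome as the
interplay of two condensin activities on a coarse-grained chromatin
fiber.

**Chromatin fiber.** The fiber is a bead-spring chain; one bead of
diameter sigma represents 20 nm of fiber carrying 2 kbp (an intermediate
choice between a 10-nm and a 30-nm fiber).  Adjacent beads are joined by
stiff harmonic bonds `U = K (r - r0)^2` with `K = 100 kBT/sigma^2`,
`r0 = 1.1 sigma`, and each interior bead carries a Kratky-Porod bending
penalty `U = K_BEND (1 + cos phi)` with `K_BEND = 3 kBT`, which gives
the bare fiber an emergent persistence length of about 3 sigma = 60 nm.
The discrete-chain prediction is `l_p = -b / ln(coth k - 1/k)` with
`k = K_BEND/kBT = 3` and bond length `b = 1.1 sigma`, i.e. 2.76 sigma =
55 nm; bond-length fluctuations in the dynamic chain push the measured
value slightly above this, to ~3 sigma.

**Topoisomerase II.** Non-bonded chromatin beads repel through a bounded
soft potential `U = A (1 + cos(pi r / r_c))`, `r_c = 2^(1/6) sigma`.
Because the barrier is finite (2A at full overlap), two strands can pass
through one another with a thermally activated rate; `A = 1 kBT` models
high topoisomerase activity (easy strand passage), `A = 100 kBT` models
its suppression.  `A` is one of the two control parameters of every run.

**Looping condensins.** Loops are static: a harmonic spring
(`K = 100 kBT/sigma^2`, rest length `1.8 sigma`) connects each loop
anchor to the chromatin bead immediately preceding the next anchor.
Loops are consecutive (back-to-back, no linkers), with lengths either
uniform or Poisson-distributed (conditioned on a 5-bead = 10-kbp
minimum, which prevents degenerate springs between bonded neighbours).
Mean loop length `L_loop` in {40, 50, 60} sigma = {80, 100, 120} kbp is
the second control parameter.  The ordered anchors define the
chromosome backbone.

**Bridging condensins.** Bridges are free beads that bind chromatin
through a truncated, energy-shifted Lennard-Jones attraction: 3 kBT to
generic chromatin, 8 kBT to loop anchors, with cutoff 1.8 sigma.
Bridge-bridge interactions are purely repulsive (WCA, 1 kBT): all
clustering is emergent bridging-induced attraction, not direct
stickiness.  A note on the attractive cutoff: a Lennard-Jones potential
truncated at its minimum `2^(1/6) sigma` exerts no attractive force at
all, so the bridge-polymer terms use the 1.8 sigma cutoff conventional
in bridging-induced-attraction models; the bridge-bridge term keeps the
`2^(1/6)` WCA form.  This choice affects absolute energies, not the
qualitative phase behaviour.

**Dynamics.** All particles follow the underdamped Langevin equation
with `m = gamma = kBT = 1`, integrated with the BAOAB splitting at
`dt = 0.01`.  BAOAB reduces exactly to velocity Verlet at `gamma = 0`
(used by the energy-conservation test) and samples configurations with
near-exact accuracy at `gamma dt = 0.01`.  The thermostat noise uses
variance-matched uniform deviates (`sqrt(3) U[-1,1]`) from a seeded
xorshift64* stream — the standard Langevin-thermostat shortcut: the
first two moments are exact and the stationary velocity distribution is
Gaussian by the central limit theorem over the ~100 kicks of one
relaxation time (long-run kinetic temperature verified within 1%).  On
the production force path the soft-potential `sin` is evaluated by a
polynomial with ~5e-7 absolute error; energy evaluations and the
gradient-consistency oracle use exact library trigonometry.  Times map to physical units
through the Brownian time `tau_B = 3 pi sigma^3 eta / kBT = 2.7 ms` at
T = 300 K and nucleoplasm viscosity 150 cP (commonly rounded to ~3 ms;
the package returns the unrounded value so step conversions do not
compound rounding).  Forces map through `kBT/sigma = 0.207 pN`.

Non-bonded forces use a Verlet list built on a cell grid with
species-pair-resolved list cutoffs (pair cutoff + 0.6 sigma skin),
rebuilt when any particle has moved half the skin.  Directly bonded
pairs (chain, loop, centromere springs) are excluded from non-bonded
terms; second neighbours along the chain are not, which adds a small
extra self-avoidance consistent with the bounded soft potential.
Pair Lennard-Jones forces are capped at 1000 kBT/sigma, which only
affects accidental start-up overlaps (the cap corresponds to distances
below ~0.78 sigma that equilibrium configurations never visit).
Coordinates are never wrapped; the periodic box enters only through
minimum-image distances, so every stored frame is directly usable by
the shape observables.

A single integer seed drives all randomness (initial velocities, bridge
placement, thermal noise, Poisson loop draws); runs are single-threaded
and bit-reproducible.

## Protocols

**Compaction.** The bottlebrush is constructed in a near-relaxed
geometry (loops laid on circles around a straight axis, rotated by the
golden angle) and equilibrated with bridges interacting only sterically;
the bridge-chromatin attraction is then switched on (t = 0) and the run
continues until the radius of gyration plateaus.  Plateau criterion:
the windowed mean of R_g over three consecutive chunks changes by less
than 1% between windows; each phase also carries a configurable time
budget, and hitting the budget without a plateau emits a warning with
the partial result.

**Box and bridge placement.** The cubic periodic box defaults to 1.3x
the initial bottlebrush extent — comfortably clear of periodic
self-interaction (all pair cutoffs are < 2.5 sigma) while keeping bridge
diffusion onto the polymer inside a desk-scale budget.  Bridges are
seeded uniformly over the polymer's bounding box (+2 sigma): the
steady state does not depend on the approach path, and seeding bridges
across a much larger empty box merely prepends dead diffusion time
(measured: with a 4x box, bridge capture alone takes ~2 x 10^6 steps).

**Micromanipulation.** Extension-retraction cycles apply constant equal
and opposite forces (2-9 pN mapped, i.e. ~10-43 kBT/sigma) to the two
terminal backbone anchors along their joining line, re-evaluated every
step, then release.  Constant-force pulling differs from the
constant-velocity protocol of real micromanipulation; the two agree in
the thermodynamic limit and the structural response is expected to be
equivalent.

**Perturbations.**  Global condensin I knockout: loop length x2,
bridge count /2; condensin II knockout: loop length /2, bridge count
x2 (the paper-family convention of halving/doubling the bridge pool;
the factor-2 loop rescaling is this package's symmetric choice, as only
the direction — longer/shorter — is biologically constrained).  Common
fragile sites are modelled locally: "removal" deletes two adjacent
loop-closure springs (cytological-lesion scenario); "merge" replaces
three consecutive loops by one triple-length loop (irregular-FISH
scenario); both keep the bridge pool unchanged.  Simulated FISH probes
are bead-index intervals flanking the perturbed locus; the reported
signal is the time-averaged distance between the probe centres of mass.
Sister chromatids duplicate the chromatid, join the central loops with
10 homologous-bead springs, and double the bridge pool.

## Observables

* **Shape**: gyration tensor eigenvalues; the reported axes
  `lambda_1 <= lambda_2 <= lambda_3` are the eigenvalue square roots, so
  `R_g^2 = sum(lambda_i^2)` holds on every frame, and acylindricity
  `Ac = lambda_2 - lambda_1` carries length units.  (The alternative
  eigenvalue-difference convention is monotone-equivalent for every
  comparison made here.)
* **Backbone stiffness**: tangent-tangent correlations of the anchor
  backbone coarse-grained to every 5th or 10th anchor (the decimation
  smooths local crumpling of compacted backbones); local stiffness is
  the mean cosine of the turning angle between successive coarse
  segments.
* **Contact scaling**: P(s) with a 3.5 sigma contact cutoff (beyond the
  1.8 sigma attraction range; exposed as a parameter), log-uniform bins,
  and a power-law fit over one intermediate decade, by default 100 kbp
  to one tenth of the polymer length.  Compacted loop-containing
  chromosomes show the mitotic `P(s) ~ s^(-1/2)` there, while both the
  pre-compaction bottlebrush and unlooped controls are much steeper.
* **Clustering**: single-linkage connected components of bridges at
  1.3 sigma (just beyond the 2^(1/6) ~ 1.12 sigma WCA contact), the
  classic measure of axial condensin clusters.
* **Valence**: mean number of chromatin beads within 1.1 sigma (22 nm)
  of a bridge; ~3 in the compacted state, which is what makes a bridge a
  bridge.
* **Extension/width**: end-anchor distance, and twice the RMS radial
  distance of chromatin from the principal gyration axis.
* **Bristle repulsion**: the scaling estimate
  `F ~ (T/lambda) sqrt(N a / (pi lambda))` for the force per unit axial
  length between bottlebrush bristles, used for ratio arguments only —
  its concavity in N explains why Poisson-distributed loops compact
  further than uniform loops at the same mean.

## Desk-scale problem sizes

The package's own validation campaigns are reduced-scale versions of
the production conditions, chosen to keep full test and acceptance runs
on a single CPU:

* contact-scaling campaign: 100 Poisson loops of mean 80 kbp
  (~4000 beads), A = 1 kBT (the strong-topoisomerase corner, which
  compacts fastest and shows the clean scaling regime), 150 bridges
  (the production 500-per-~333-loops density), 3 replicates, 50 tau_B
  steric equilibration each, then 2,500-4,000 tau_B of compaction run
  in 500-tau_B chunks inside a fixed wall-clock allocation — the
  contact exponent is in its slowly-evolving late regime over that whole
  step range, so extra compute buys convergence margin rather than a
  different answer; the exponent is fitted per replicate on the final
  500 tau_B and averaged;
* persistence-length campaign: four free 200-bead chains started from
  equilibrium worm-like-chain samples (a straight-rod start would need
  the full Rouse time to forget its global orientation), 50 tau_B
  equilibration + 600 tau_B sampling, exponential fit over tangent
  separations 1-6 bonds (one decade of decay);
* trend suites (loop-length, topoisomerase, loop-statistics, knockout
  and fragile-site comparisons): 12-20 loop miniatures with 10 replicate
  seeds and one-sided rank tests.

At these scales the compaction runs reach the valence and shape plateaus
but remain short of the fully coarsened bridge-cluster steady state of
production-scale simulations; the contact-probability exponent is
measured in the late, slowly-evolving regime.  Cluster counts in
particular are still drifting downward when the campaigns stop, so
absolute cluster sizes from desk-scale runs should be read as lower
bounds.

Micromanipulation cycles are creep-limited: under a constant ~9 pN end
force the extension of a compacted cylinder grows by thermally
activated unzipping of bridged contacts, roughly +0.3x of the initial
length per ~2,700 tau_B in the reduced systems.  Full-scale cycles
extend over ~1e5 tau_B and reach several-fold extension; reduced cycles
of 1,000-3,000 tau_B reach about twofold.  The qualitative elasticity
signatures — substantial extension, bridging-driven recovery after
release, and the failure to recover when bridges are absent — are all
reproduced at desk scale; the absolute fivefold extension is not, and
the corresponding check is expected to fail at reduced durations.
Recovery comparisons are only meaningful against a well-converged
starting cylinder: if the pre-cycle compaction has not plateaued, the
chromosome keeps compacting through the cycle and relaxes to a length
shorter than where it started.

## What the synthetic conditions do not capture

The generator emulates the model's own study conditions, not real
nuclei: there is no replication machinery, no helical winding of the
backbone (the model produces only the weak helicity inherent to
bottlebrushes), no nested or dynamic loops (loop extrusion is out of
scope; loops are pre-formed and static), no hydrodynamic interactions,
and bridging and looping condensins are distinct species.  Passing
tests therefore demonstrate the self-consistency of the model and the
correctness of its implementation, not quantitative agreement with any
particular experimental chromosome.

## Numerical choices and degenerate inputs

* Time step 0.01 tau (stable for the stiffest term, the K = 100 bonds,
  at dt*omega ~ 0.14); energy-conservation checks run at dt = 0.002
  where the bounded shadow-Hamiltonian oscillation is below the 1e-4
  drift tolerance.
* Rank-deficient bead clouds (lines, planes) yield zero axes rather than
  errors; zero-length coarse segments are excluded from stiffness
  statistics; empty P(s) bins are excluded from fits.
* Observables that need unwrapped coordinates raise
  `WrappedCoordinateError` when any bond exceeds half the box.
* The Poisson loop sampler resamples draws below the 5-bead minimum
  (truncation, not clipping, so the conditional mean stays above the
  nominal mean by a negligible amount at mean >= 40).
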