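# Methods

`kinforage` is a desk-scale re-creation of a classic experimental-evolution
design: groups of neural-network-controlled foraging robots evolve under
precisely controlled within-group relatedness *r* and cost/benefit ratio
*c/b*, so that Hamilton's rule (*rb* − *c* > 0) can be tested
quantitatively rather than anecdotally.  This note records the model, the
parameters that matter, the design choices that were genuinely open, and
what the desk-scale results do and do not show.

## Genomes and controllers

Each agent's genome is 33 genes of 8 bits (values 0–255), mapping linearly
onto the 33 connection weights of a feed-forward tanh network:
6 sensor inputs + 1 bias input (fixed at −1) → 3 hidden → 3 outputs
(left wheel, right wheel, share signal).  The stated layer sizes only sum
to 33 weights if the bias input feeds both the hidden layer (7×3 = 21) and
the output layer (4×3 = 12); that wiring is adopted.

Two choices here are ours, not inherited facts:

* **Weight range W.** Genes decode as *w* = *W*(2*g*/255 − 1) with
  default *W* = 1.  A symmetric unit range keeps pre-activations of the
  7 bounded inputs within a few units, i.e. tanh stays in its responsive
  regime.  *W* is configurable.
* **Gene→slot order.** Genes 0–20 fill the input→hidden matrix row-major
  (input-major), genes 21–32 the hidden+bias→output matrix row-major.
  Any fixed order is equivalent under evolution; this one is frozen
  because serialized genomes must decode identically forever.

Bits are most-significant-first within a gene, so "the third bit" carries
weight 32; the medium-effect screen mutation (third-bit flip) therefore
always changes a gene by exactly ±32.

## Arena model

The original system used a physics-grade robot simulator.  Reproducing
contact dynamics is neither possible from the published description nor
necessary for the question being asked — the evolutionary claims depend on
the payoff structure, not on friction coefficients.  The arena here is a
declared kinematic model:

* 50×50 cm square, one white wall (top) and three black walls; 8 robots
  (radius 1.3 cm) and 8 food items (radius 1.0 cm) per trial; items must
  be pushed into a 4-cm-deep band along the white wall.
* Differential drive: wheel speeds are `max_wheel_speed` (4 cm/s) times
  the two motor outputs; wheel track equals the robot diameter.  Euler
  integration at 0.1 s steps, 600 steps per 60-s trial.
* Quasi-static pushing: a robot overlapping an item displaces it along
  the centre line (no momentum); robot–robot overlaps are resolved by one
  symmetric relaxation pass; everything is clipped to the walls.
* Sensors: three short-range IR cones (−45°/0°/+45°, 30° aperture, 3 cm)
  seeing robots, items and walls; one long-range IR cone (0°, 6 cm)
  seeing robots only — this asymmetry is what lets controllers tell
  robots from items; two vision channels test whether a ray through the
  centre of each half of a 60° forward field reaches the white wall
  unoccluded by robots.  IR proximity is linear: +1 at contact, −1 at or
  beyond range.
* The "4-cm-wide target zone along the white wall" is ambiguous between
  a 4-cm segment of wall and a 4-cm-deep band along the whole wall; the
  band interpretation is adopted (the whole white wall is the target).
* A delivered item is credited to the last robot that pushed it (nearest
  robot if it was never pushed — possible only in degenerate layouts,
  since items never start inside the band) and is labelled shared if
  that robot's share output is positive **at the delivery step**.  A
  per-item decision at delivery time is the most direct reading of "the
  third neuron determined whether the collected item was shared";
  integrating the share signal over the trial would be the alternative.
* Start layouts are uniform rejection-sampled non-overlapping positions,
  seeded; items start outside the target band.  Delivered items are
  removed, capping a trial at 8 deliveries.

None of the geometric defaults (time step, radii, speeds, cone angles)
are published values; they are package defaults chosen once for a sparse
50×50 arena, and all are configurable.  The inner loop is compiled with
numba and vectorized over independent trial "worlds", so a full
generation (200 groups × 10 trials = 2,000 worlds) is one kernel call.

## Relatedness

Groups of *n* = 8 are built from clone types with copy numbers
(k₁, …): the five named treatments are r0 = {1×8}, r25 = {3,3,2},
r50 = {6,1,1}, r75 = {7,1}, r100 = {8}.  Founders are drawn at random
from the population each generation, so founders are treated as
genetically distinct and identity arises only through cloning.  With
*m* groups and self-pairs excluded,

    p_group = Σᵢ (kᵢ/n)(kᵢ−1)/(n−1)
    p_pop   = m Σᵢ kᵢ(kᵢ−1) / (N(N−1)),  N = mn
    r       = (p_group − p_pop) / (1 − p_pop)

computed in exact rational arithmetic.  At *m* = 200 this gives
r = 1, 0.7492, 0.5346, 0.2492 and 0 for the five schemes.  The 1:7 value
0.7492 matches the originally reported value exactly; for {6,1,1} and
{3,3,2} the original study reports ≈0.5357 and ≈0.2468, which are not jointly consistent
with any single pair-regression formula that also yields 0.7492
(0.5357 is exactly p_group for {6,1,1}, i.e. the population-baseline
correction dropped).  The implementation documents its formula, matches
a brute-force enumeration oracle over all ordered pairs to machine
precision, and deliberately does not force-match 0.5357/0.2468.  The
analytic value labels treatments; an empirical regression estimator over
genotype bit matrices (`queller_goodnight_estimate`) is provided as a
verification tool and converges to the analytic value on random-founder
populations.

## Payoffs, fitness and selection

A kept item is worth *c* to the collector; a shared item is worth *b*
split equally among the 7 group-mates (the collector gets nothing).
Only *c/b* matters for the direction of selection, so payoffs are
normalized to *b* = 1, *c* = ratio; the original study's own normalization
constant is not recoverable from its published description, and any positive choice only
rescales selection intensity.  Inclusive fitness over an evaluation
(10 trials by default) is

    fᵢ = c·n_selfish,ᵢ + (b/7)·Σ_{j≠i} n_shared,j .

The five default *c/b* levels are {0.01, 0.2468, 0.5357, 0.7492, 1.0},
so the r = c/b diagonal of the 5×5 treatment grid exists by design; only
0.01 (chosen over 0 to avoid extinction when nothing is worth
collecting), 0.25 and 0.75 are explicitly attested, the rest follow the
relatedness-matching construction.

Generation turnover: roulette-wheel selection with replacement over all
m·n individuals (reproductive competition is population-wide), founders
paired sequentially for single-point bit-boundary crossover
(p = 0.005 per pair), per-bit mutation (p = 0.005, i.e. 0.04 per gene),
then cloning into groups per the composition scheme.  One founder is
drawn per clone-type slot, so relatedness is re-established exactly
every generation.  If total fitness is zero (possible early at
c/b = 0.01 with unrelated groups), selection falls back to uniform
random draws rather than extinction.  The altruism level of a group is
A = n_a/(n_a + n_s); groups that delivered nothing are undefined and
excluded from population means.

An exhaustive-enumeration oracle (in the test suite) confirms the
design's core prediction at miniature scale: with a toy share/keep
locus, one item per individual and exact expectation over all founder
allele configurations, the one-step expected change in share-allele
frequency is positive when r exceeds c/b by a margin and negative when
it falls below — Hamilton's threshold emerges from the payoff and
selection scheme alone.

## Mutation-effect screens

All three screens use the ±32 third-bit flip (the median size of the
mutations experienced during evolution) and per-trial samples of the
focal individual evaluated inside its own group, with identical layout
seeds before and after mutation:

* **Pleiotropy** — Wilcoxon rank-sum tests (5% level) on performance
  (items collected by the focal per trial) and altruism (share fraction
  of those items, undefined trials dropped); individuals collecting
  nothing in any trial before and after mutation are excluded.
  Classification: performance-only / altruism-only / both / neither.
* **Epistasis** — four conditions F(0), F(A), F(B), F(AB) built from two
  medium-effect mutations at distinct random genes;

      z = [(mean F(AB) − mean F(B)) − (mean F(A) − mean F(0))]
          / sqrt((s²₀ + s²_A + s²_B + s²_AB)/trials)

  with |z| > 2 significant.  The exact z formula used originally was
  not published in recoverable form; this contrast-of-differences form is
  our declared interpretation of "z scores based on the SD and mean
  fitness", and it is exactly zero for any additively constructed
  fitness.  Requiring gene B ≠ gene A prevents the second mutation from
  undoing the first (the AB genotype would otherwise collapse to 0).
* **Weak selection** — fraction of mutations whose 100-trial mean
  performance or altruism changes by more than 25% relative to the
  pre-mutation mean; a zero pre-mutation mean counts as a large change
  exactly when the post-mutation mean is positive.

The originally published screen *counts* and percentages depend on
genomes evolved in the original physics engine and are out of scope; the
screens' mechanics, bookkeeping (tested + excluded = sampled) and
degenerate-case behaviour are what this package claims and tests.

## Drift statistic and grid statistics

Across replicate populations of one treatment, F = Var(p)/(p̄(1 − p̄))
with the sample variance (divisor n − 1; the original study does not
specify the divisor) and p̄ the mean final altruism; F is undefined when
p̄ ∈ {0, 1}.  Grid statistics (`results_statistics`): last-10-generation
means per replicate, one-sample Wilcoxon of diagonal-cell altruism
against the neutral initial value 0.5, Mann-Whitney comparisons of F
between the diagonal and off-diagonal sign classes, and Pearson
correlations of final altruism with r − c/b separately on each sign
branch (the mutation–selection-balance pattern).

## Problem sizes

Defaults reproduce the original experimental scale (m = 200 groups, 500 generations,
20 replicates, 10 trials per evaluation); the package's own validation
runs are scaled down.  The standing qualitative check is a 3×3 grid
{r0, r50, r100} × {0.01, 0.5357, 1.0} with m = 20, 100 generations,
5 replicate populations per cell and 3 evaluation trials per group per
generation: median final altruism must order below-diagonal < diagonal <
above-diagonal, and the diagonal class must show the largest
between-replicate F.  Generation-0 altruism of uniform-random genomes is
checked at full population scale (10 seeded populations of 200 groups,
10 trials each) against the neutral expectation 0.5 ± 0.05.

## What the synthetic conditions do not show

The kinematic arena has no momentum, friction, sensor noise or camera
imagery; evolved controllers exploit this simplified physics and their
absolute foraging efficiencies are not comparable to the original
system's.  Scaled-down populations (m = 20) drift more and equilibrate
at less extreme altruism than m = 200 populations would; the package's
passing tests establish the direction and ordering of effects, not the
original study's absolute endpoint values, which are out of scope.
Mann–Whitney comparisons over three F values per class are at the edge
of their resolution (the one-sided exact minimum p is 0.05); the class
medians carry the claim.
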