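# Methods

`ssir` groups a pool of partial serial-crystallography datasets into
internally isomorphous subsets so that one pair of groups — a less- and a
more-derivatized sub-population from a single heavy-atom soak — can be used
as the native/derivative pair of a single isomorphous replacement (SIR)
experiment.  This note records the models, the defaults and the reasoning
behind the choices that were genuinely open.

## The grouping model

Each partial dataset is a few degrees of rotation data from one microcrystal:
incomplete, low multiplicity, on its own scale.  The genome of the genetic
algorithm (GA) is a label vector assigning each of the n datasets to one of K
groups (default K = 4: with a single soak, both sub-populations and outliers
coexist in the pool, and spare groups absorb crystals that belong to
neither).  Fitness of a partition is the mean over groups of

    (100 − 100·R_meas) w_R + ⟨I/σ⟩ w_I/σ + 100·CC½ w_CC
      + 100·completeness w_C + multiplicity w_M

plus an isomorphism term for the single most contrasting group pair,

    ISO = w_iso · min(R_inter / R_intra_avg , cap),   cap = 10.

* `R_inter` — between-group R on merged intensities over the common unique
  reflections, Σ|I_A − k·I_B| / Σ(I_A + k·I_B)/2, after least-squares scaling
  k of B onto A.  Inside the GA the scaling direction is canonicalized (the
  lexicographically smaller group is the reference) so the value is a pure
  function of the unordered pair; the residual directional asymmetry is a few
  percent and a fully symmetrized option exists (`iso_symmetric`).
* `R_intra_avg` — the noise floor against which the contrast is judged.  Two
  readings exist: the mean of the two merged groups' inner-shell R_meas
  (`iso_intra_mode="merged"`), or the mean of the member datasets' own
  inner-shell R_meas (`"dataset"`, the default).  The per-dataset reading is
  preferred because individual-dataset statistics are what per-crystal
  integration programs report, and because it is partition-independent: with
  the merged-group denominator the GA can cherry-pick tiny, mutually
  coherent groups whose denominator is artificially low, saturating the
  capped ratio and wrecking recovery on weak-signal pools.  We observed
  exactly this pathology in simulation.
* The cap encodes the classical sanity check that the absolute inter-dataset
  R must not be excessively high (gross non-isomorphism must not be rewarded
  without bound).
* Undefined ingredients (too few common reflections, no multiply-observed
  inner-shell reflection) are never coerced to 0: a group with an undefined
  weighted statistic receives the penalty fitness (−10⁶ by default), and a
  partition with no defined pair is penalized likewise.

A partition is feasible when every group has at least `min_group_size` (2)
members; infeasible partitions are representable but carry the penalty.

## Merging statistics

Datasets are first placed on a common scale: the dataset with the highest
unmerged ⟨I/σ⟩ is the reference, and each dataset gets a single linear scale
from an inverse-variance weighted least-squares fit on shared unique
reflections (transitively, breadth-first through the overlap graph, for
datasets that do not overlap the reference directly; no per-dataset
B-factor).  Merging is the inverse-variance mean per unique reflection.
R_merge / R_meas / R_pim use the unweighted per-reflection mean and run over
reflections with ≥ 2 observations; CC½ is the mean Pearson correlation of
two random half-set merges over 20 seeded exact half-splits (the definitional
quantity rather than the σ–τ closed form, so it is directly oracle-testable);
completeness counts observed unique reflections against the enumerated
unique set of the pool's resolution range; shells are 10 equal
reciprocal-volume bins and "inner shell" means the lowest-resolution bin.
Negative merged intensities are retained everywhere.

Inside the GA the same R/⟨I/σ⟩/completeness/multiplicity formulas are
evaluated by a compiled kernel (cross-checked against the reporting module to
1e−12 in the tests).  CC½ inside the fitness is a cheaper deterministic
estimator: 8 pre-drawn random half-splits of the group's member datasets,
correlating the two half-pool merges.  A fitness needs a stable ranking
signal, not a publication statistic; reported tables always use the full
per-observation `cc_half`.

## The GA

Tournament selection (size 3), uniform crossover (p = 0.8), per-gene mutation
to a uniformly random different label (p = 1/n), elitism (2).  All randomness
derives from one mandatory seed, so trajectories are byte-identical across
reruns.  Group fitness is cached by the (unordered) member set — the GA
re-evaluates many shared groups — and evaluation is a pure function of the
label vector, independent of evaluation order.  After the last generation the
best partition is polished by a deterministic steepest single-dataset
reassignment pass until locally optimal (`polish=True`); on simulated pools
this reliably converts near-misses (one or two misassigned crystals) into
exact recoveries at a fraction of the cost of more generations.  Library
defaults are population 100 × 50 generations; the acceptance tests use
explicitly stated smaller budgets (e.g. 60 × 30) to fit their runtime limits.

The best pair of a partition is the unordered group pair with the maximal
ISO ratio.  Isomorphous differences alone cannot tell which group is native
and which is derivative, so every export lists both orderings.

## The synthetic-data generator

`simulate_pool` emulates the statistical structure of the experiment, not the
optics: a point-atom "protein" (120 random atoms, f = 7 e, B = 15 Å²) plus
heavy sites (f = 60 e) expanded over the full space group; per-crystal heavy
occupancy drawn from overlapping sub-population distributions (native
μ = 0.05, σ = 0.05; derivative μ = 0.7, σ = 0.15 — soaks partially derivatize
the "native" crystals too); per-axis fractional cell jitter (σ = 0.001,
optionally with different sub-population centres); resolution-dependent
intensity non-isomorphism; Bernoulli coverage (0.5) with 1 + Poisson
within-crystal multiplicity (mean 2); lognormal per-crystal scales (σ = 0.2);
and counting noise σ = √(I + floor) after calibrating the pool-mean intensity
to 100 detector counts.  That calibration matters: per-dataset ⟨I/σ⟩ then
lands in the 4–9 range typical of serial microcrystal data; with arbitrary
|F|² units the pools came out two orders of magnitude too clean, making
per-dataset noise floors meaninglessly small.

Non-isomorphism uses a rigid-contents model: when one cell edge of length a
changes by fraction ε with the (Cartesian) contents fixed, atoms uniform in
a sphere of radius a/2, the mean fractional intensity change of acentric
reflections at resolution d is

    m(ε, d, a) = (2/√π)(π/√15) · ε·a/d  ≈ 0.9153 · ε·a/d,

which reproduces the classical benchmark that a 0.5% cell change produces a
~15% intensity change at 3 Å (15.3% here).  `apply_non_isomorphism`
multiplies each intensity by (1 + m·z), z zero-mean Gaussian scaled so that
E|ΔI|/I = m, clipped at zero — the statistical effect of cell variation at a
fraction of the cost of explicit coordinate re-expansion.

What a green test does establish: the statistics, the fitness, the GA and the
Patterson check behave correctly on data with the stated covariance
structure.  What it does not: robustness to indexing ambiguity, wedge
geometry, absorption, radiation damage or detector artefacts, none of which
are simulated.

## Difference Patterson surrogate

Downstream substructure determination is out of scope, so "phasing success"
is replaced by a desk-scale surrogate: ΔF = √max(I_deriv,0) − √max(I_nat,0)
after inter-group scaling (least-squares by default; an exactly
swap-antisymmetric norm-ratio scaling is available), a difference Patterson
P(u) = Σ ΔF² cos(2π h·u)/N by direct summation on a grid of step d_min/3,
and a peak search outside a 0.1·min-cell-edge origin sphere with heights in
map σ above the mean.  Recovered peaks are matched against the
symmetry-expanded interatomic vectors of the true heavy sites (minimum-image,
within 1.5 grid steps).  On 20-crystal P1 pools with two sites the true
cross-vector ranks in the top peaks at ~15σ while heavy-atom-free null pools
top out near 4σ.  One caveat learned in simulation: the surrogate needs the
heavy contribution to be perturbative (a realistically sized protein);
if heavy atoms dominate the total intensity, the inter-group scaling itself
distorts the differences.

## Numerical choices and degenerate inputs

* Undefined statistics propagate as `None`, never 0.
* σ ≤ 0 observations are dropped at parse time with a logged count; no other
  outlier rejection.
* ASU convention: lexicographically greatest symmetry equivalent including
  Friedel mates (no anomalous signal anywhere).
* Tie-breaks: reference choice — lexicographically smaller id; best pair —
  smallest group indices; all argmax operations use first-index semantics.
* Degenerate resolution ranges (single-reflection pools) pad the shell
  boundaries by ±0.1%.
* Space-group support is a closure-tested built-in table (P1, P212121,
  P43212, I213, P6122); general symbol parsing is out of scope.

## Known limitations

* Single linear scale per dataset; no resolution-dependent (B-factor)
  scaling.
* The ISO term enters through the best pair only; with more than one
  derivatized sub-population a multi-pair extension would be needed.
* The GA fitness CC½ estimator splits datasets, not observations (see above).
* Patterson peak positions are nearest-grid; no sub-grid interpolation.
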