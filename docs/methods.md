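# Methods

`wfscale` measures the bias introduced by population-size rescaling
("Q-scaling") in forward-in-time Wright-Fisher simulations.  This note
documents the model, the estimators, the numerical choices, and what the
desk-scale test battery does and does not establish.

## The simulation model

The engine is an individual-based diploid Wright-Fisher simulator:
generations are non-overlapping, mating is random among hermaphroditic
individuals (selfing permitted — two independent parent draws per
offspring), and the population size follows the configured demographic
schedule regardless of fitness.  Each offspring draws two parents with
probability proportional to fitness and receives one recombinant gamete
from each.

* **Fitness** is multiplicative across sites: a homozygous site contributes
  `1+s`, a heterozygous site `1+h*s`, each factor clamped at 0 (so a lethal
  genotype zeroes the product).  `h = 0.5` in every catalog model.  Fitness
  is accumulated in log space; if the product still overflows (stacked
  Q-multiplied coefficients at aggressive Q), the replicate aborts with an
  "infinite fitness" diagnostic, and an all-zero-fitness generation aborts
  likewise.  The pipeline logs such replicates, excludes them, and reports
  the count.
* **Recombination**: crossover count per gamete ~ Poisson(r·(L−1)), with
  breakpoints uniform on [1, L−1]; segments alternate between parental
  haplotypes starting from a fair coin.  Coordinates are 0-based with
  half-open intervals; a breakpoint at i separates positions i−1 and i.
* **Mutation**: new mutations per gamete ~ Poisson(μ·L) at uniform
  positions, class (neutral / beneficial / deleterious) drawn from the
  configured mix and `s` from the class DFE.  An infinite-sites discipline
  is kept at discrete base pairs: a mutation colliding with a currently
  segregating position is redrawn.  A position fixed earlier may mutate
  again; at the simulated densities both events are negligible.
* **Bookkeeping**: mutations reaching frequency 1 become substitutions and
  are removed from haplotypes (identical observable behaviour, much
  cheaper); mutations at frequency 0 are marked lost.  For each class,
  arisen = fixed + lost + segregating at every point — a tested invariant.
* **Burn-in** starts from a mutation-free population and runs 10·N
  generations; statistics are then recorded over 4·N generations
  (constant-size models) or N_post generations after the size change.
  Mutations arising during burn-in are excluded from all statistics.

The production path compiles this update rule with numba over a sparse
haplotype representation (each haplotype is a position-sorted list of
mutation indices).  The same operations are exposed as pure-Python
reference functions (`compute_fitness`, `make_gamete`, `step_generation`),
and the test suite checks the compiled engine against closed-form and
distributional oracles: the one-step neutral martingale, Poisson mutation
counts, diversity ≈ θ, the 1/k neutral SFS, the neutral fixation
probability 1/2N, and a single-locus sweep oracle (two-sample KS).

## Rescaling

`rescale_model(m, Q)` maps N → N/Q, μ → μ·Q, r → r·Q, all time spans →
span/Q, fixed selection coefficients s → s·Q, gamma DFEs by multiplying the
mean and keeping the shape (a pure scale transform of the draws), and
lognormal DFEs by adding ln Q to the log-space location (likewise).  θ =
4Nμ and N·s are preserved.  N/Q must be an integer — the transform rejects
non-divisors rather than rounding, so a model is never silently altered.
Burn-in and recording spans are recomputed from the scaled sizes (or
divided exactly for custom spans).  Non-integer Q is accepted whenever it
divides N evenly.

The catalog ships the study models: a constant-size human-like population
(N=10,000, 25 Mb, μ=r=1.2e−8) with beneficial s=0.05 and deleterious
~Gamma(mean −0.0294, shape 0.184) mutations in several mixes (full,
no-beneficials, sparse, larger-N, strictly neutral), two-fold expansion and
contraction variants, a conditional single-sweep model (s=0.05, mid-genome,
restart on loss), and two Drosophila melanogaster models (N=1,720,600,
μ=5.49e−9, r=1.98e−8, lognormal deleterious DFE with log-scale location
9.679e−7 and scale 3.36 applied with negative sign, beneficial s=7.125e−6
or 0.01).  The Drosophila class mix is not pinned by the source tables; we
use 26% neutral with the selected remainder split 5% beneficial / 95%
deleterious, mirroring the full model's structure at a catalog-style
neutral fraction.  Full-scale parameterizations are expressible in config;
tests and the acceptance battery run scaled-down instances (see problem
sizes below).

For sweep models the burn-in before introducing the beneficial is
configurable (default 10·N'); the sweep's fixation-time statistics are
independent of the burn-in because the background is neutral.

## Outcome statistics

From each replicate's end state (a sample of 100 random individuals, or N
if smaller) four summaries are computed:

1. **Unfolded SFS** per mutation class over derived-allele counts 1..2n−1
   (199 entries at n=100; the ancestral state is known to the simulator).
2. **LD profile**: haplotypic r² = D²/(p_A(1−p_A)p_B(1−p_B)) over all pairs
   of sample-segregating mutations, classes pooled; if more than 5000
   mutations segregate, 5000 are subsampled first.  Pairs are averaged in
   50 equal distance bins of width L/50; empty bins are flagged (NaN), not
   zeroed.
3. **Corrected fixed fraction** per class: (#fixed / #arisen, post-burn-in)
   divided by Q, which returns the neutral class to the 1/2N scale.  The
   estimate inherits the protocol's end-of-run censoring (late-arising
   mutations have not had time to fix); an extended-window option exists for
   uncensored checks.  A class with no arisen mutations is flagged
   undefined, never coerced to 0.
4. **Fixation-time histograms** per class of the corrected times
   (scaled sojourn × Q), on a bin width fixed for the whole experiment:
   the first baseline replicate (by seed order) with fixations of the class
   sets width = its maximum corrected time / 20; bins are half-open
   [k·w, (k+1)·w) with one overflow bin.  The reference replicate is
   recorded in the experiment manifest.

Per-replicate scalar means feed the percent-error measures: the mean
corrected fixation time over the replicate's fixations, the mean sample
frequency over segregating mutations of the class (sample, not population,
frequencies — the same 100-individual sample as the SFS), and the mean r²
over bins weighted by pair count.

## Deviation measures

With μ̄ the across-replicate average of the per-replicate means:

* **Percent error.**  The directional definition
  `mean_percent_error = 100·(μ̄_unscaled − μ̄_scaled)/μ̄_unscaled` is positive
  when rescaling lowers the mean and undefined (flagged, never 0) when the
  baseline mean is 0.  Report tables instead carry `percent_change`, its
  negation — positive when rescaling raises the mean — because that is the
  orientation the published comparison tables in this literature actually
  use (a mean fixation time rising from 600 to 615 generations appears as
  +2.5%).  Both functions are public and every report records which
  orientation it carries.
* **KL divergence** (fixation-time histograms and SFS): bins are averaged
  across replicates, one pseudo-observation is added to every bin of both
  averaged histograms, each is normalized to a probability vector, and
  D_KL(unscaled‖scaled) = Σ p·ln(p/q) in nats.  The pseudocount (default 1,
  recorded in the report) keeps D_KL finite when the scaled side has an
  empty bin; the natural log is our reading of an unspecified base.
* **LD RMSE**: root mean squared difference of the replicate-averaged bin
  means over the 50 distance bins; bins empty on either side are excluded
  from numerator and denominator (with all 50 populated this is the plain
  /50 form).
* **Bootstrap**: each of B=1000 resamples redraws both replicate sets with
  replacement at original sizes and recomputes every measure end-to-end;
  reports give the mean and SD over resamples.
* **Subsample stability**: deviation measures recomputed from random
  subsets (without replacement) of 100 or 10 replicates per side, repeated
  1000 times, yield the sampling distribution a researcher would face with
  few replicates.

## Distinguishability protocol

For each Q and each of four feature sets — concatenated per-class SFS,
the 50 LD bin means (empty bins zero-filled and flagged), one corrected
fixed fraction per class, concatenated per-class fixation-time histograms —
a logistic regression (L2, C=1.0, 100-iteration cap, features standardized)
and a random forest (100 trees, Gini, unlimited depth, raw features) are
trained to label replicates scaled vs unscaled.  Hyperparameters are pinned
rather than delegated to library defaults so results are stable across
versions.  Classes are truncated to equal size and split 80/20 with
balanced classes in both partitions, so chance accuracy is 0.5; accuracy is
reported on the held-out 20% only.  A label-shuffle canary and an
iid-two-sample null keep the protocol honest.

## Randomness and reproducibility

One root seed drives an experiment.  Per-replicate streams derive from
counter-based `SeedSequence` spawning (so replicates are order-independent),
and analysis stages (LD subsampling, bootstrap, classifier splits) use
separately derived streams.  Identical configs reproduce outputs
byte-for-byte; replicate summaries are stored as one JSON each and reloaded
on resume.  The compiled kernel holds its own seeded generator, and
`run_replicate(model, seed)` is deterministic.

## Problem sizes used in tests and the acceptance battery

The simulator is its own data generator; no external data enter.  The
battery runs scaled-down instances chosen to keep the full suite on a
single CPU while leaving the estimators in their calibrated regimes:

* conditional sweeps at N=10,000 vs (N/Q, s·Q), 1000 replicates per arm —
  the one published table row that is exactly reproducible at desk scale;
* the full model at Q=20 with the genome reduced from 25 Mb to 1 Mb,
  100 replicates (the corrected neutral and deleterious fixed fractions are
  per-mutation rates, insensitive to L);
* strictly neutral models at N=200–1000 with 50 kb genomes for the
  diversity, SFS and null-pipeline checks.

What desk scale does **not** establish: the full-scale magnitudes of the
non-sweep table rows and classifier-accuracy figures (25 Mb genomes,
N=10,000, 1000 replicates) and all Drosophila rows — those depend on
absolute mutation counts per replicate and are out of reach on one CPU.
The property checks (θ-invariance, oracle equivalence, metric closed forms,
null calibration, subsample stability) verify the machinery those results
rely on, not the results themselves.

## Numerical and design choices

* Sign conventions: see percent error above; the published tables' sign
  conflicts with their printed formula, and we expose both orientations
  rather than silently picking one.
* SFS is unfolded; 199 features for a 100-individual sample implies counts
  1..199, which fixes the convention.
* LD pools all mutation classes; r² pairs with a monomorphic column are
  excluded, not scored 0.
* The KL pseudocount, log base, LD empty-bin policy, and MPE undefined
  flags are recorded in report metadata so externally produced summaries
  can be compared like-for-like.
* Engine capacities (haplotype width, site table, record table) are
  heuristic and grow-on-demand: a capacity overflow re-runs the replicate
  from its seed with doubled capacity, leaving results unchanged.
* The single-locus sweep oracle evolves genotype counts by multinomial
  sampling at the fitness-weighted gamete frequency — mathematically
  identical to individual-based parent sampling, and exact for the
  conditional (restart-on-loss) protocol.

## Known limitations

* No tree-sequence recording, recapitation, coalescent burn-in,
  non-Wright-Fisher dynamics, sex chromosomes, or variable recombination
  maps.
* Windowed diversity statistics (π, Tajima's D) are not part of the outcome
  set.
* The fixed-fraction estimator is deliberately censored exactly as in the
  study protocol; use the extended-window option when an unbiased fixation
  probability is needed.
* Selfing is allowed; with N in the hundreds or more the marginal allele
  dynamics are indistinguishable from obligate outcrossing, but small-N
  inbreeding effects differ.
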