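# Methods

`wolfped` reconstructs multigenerational pedigrees of a small,
non-invasively monitored wolf population from replicate microsatellite
genotypes, and quantifies how reliable those reconstructions are.
This note documents the models, the estimation procedure, the
synthetic data the package tests itself against, and the numerical and
design choices a user should know about.

## Data model

A *sample* (usually a scat) is genotyped at a panel of microsatellite
loci in replicate PCRs.  A replicate call is an unordered allele pair
or a failure.  An *individual* is a cluster of samples with matching
multilocus genotypes; its consensus genotype per locus is the majority
call over its samples.  Parentage is estimated between individuals.

### Consensus calling

Each sample is amplified in a triplicate per locus.  A heterozygous
genotype is accepted when the same heterozygous allele pair is
observed in at least two of the three replicates; a homozygote only
when all three replicates show the identical homozygous call (a failed
replicate therefore blocks a homozygote).  An unresolved locus
triggers a second triplicate, evaluated on its own (a pooled
six-replicate evaluation is available via `ConsensusRules(pooled=True)`);
a locus unresolved after both triplicates is treated as missing.  The
pair-observed-together reading of the heterozygote rule is deliberate:
counting the two alleles separately would accept the conflicting
dropout pattern {AA, AB, BB}, in which two replicates show opposing
homozygotes.

### Individual identification

Two multilocus genotypes are declared the same individual when they
disagree at no more than two alleles in total, with at most one
mismatching allele per locus — two errors concentrated at one locus
are more plausibly a true genotype difference than two independent
typing errors.  Comparisons with fewer than `min_overlap = 8` shared
typed loci are NO_CALL: at the panel's diversity the random-match
probability through 8 loci is already negligible, and fewer shared
loci make the mismatch count uninformative.  Samples are clustered as
connected components of the pairwise match graph; components with an
internal pairwise conflict (possible via the transitivity of
near-matches) are flagged `AMBIGUOUS` rather than split, and cluster
consensus genotypes must be typed at ≥ 11 loci.

## Genotyping-error model

Two error classes act independently at each replicate observation of a
true genotype:

* **Allelic dropout E1** — for a heterozygote, with probability E1 one
  of the two alleles (uniformly chosen) fails to amplify; the call
  appears homozygous.
* **Stochastic miscall E2** — each apparent allele copy is then
  misread with probability E2; the misread value is drawn from the
  locus allele set proportional to population frequency, excluding the
  true allele (uniform weighting is a config option).

E2 is applied per allele copy, not per genotype; this choice is a
modelling decision of this package, exposed behind the
`error_model` module so a genotype-replacement variant can be
substituted.  Null alleles, stutter and contamination are out of
scope.  Defaults E1 = 0.04, E2 = 0.022 are the constants used for the
preliminary fit; per-locus scat-sample rates are estimated in step 2
below, while tissue/secretion samples keep literature constants (too
few repeat tissue samples exist to estimate from).

Applying per-replicate error rates to consensus genotypes (which are
built from several replicates and samples) is conservative: the true
uncertainty of a consensus genotype is smaller, so parentage
confidences are understated rather than overstated.

## Parentage likelihood

For an offspring with observed genotype `o` and a candidate pair with
observed genotypes `d`, `s`, the per-locus likelihood is

P(o | d, s) = Σ over true genotypes P(o | o_true) P(o_true | d_true, s_true) P(d_true | d) P(s_true | s)

where parental true-genotype posteriors combine the error model with a
Hardy-Weinberg prior, the offspring true genotype follows Mendelian
segregation, and the offspring observation follows the error model.
An UNSAMPLED parent (and a parent missing at the locus) is integrated
over Hardy-Weinberg, so the unsampled category is the natural limiting
case of the same formula; at zero error rates the expression collapses
to plain Mendelian transmission probabilities.  Loci multiply; loci
missing in the offspring contribute 1.  All per-locus quantities are
computed once as genotype-state matrices (observation matrix,
transmission tensor, parental posterior), so the per-candidate-pair
likelihood tables for a whole study are built in seconds.

## Pedigree MCMC

Each genotyped individual receives a (dam, sire) pair, each slot
either a sampled candidate or UNSAMPLED.  Candidates are pre-filtered:
correct sex role, not sharing zero alleles with the offspring at more
than 4 loci, alive and of breeding age (≥ 2 years) where cohorts are
known, not known to have died younger than 2 years — and first
observed strictly before the offspring (see below).

The sampler is a Gibbs sweep over offspring: the full conditional over
all legal (dam, sire) pairs is `likelihood × w(dam) × w(sire)`, where
a specific sampled candidate has categorical prior weight
1/(n_sampled + N) and the UNSAMPLED category N/(n_sampled + N), with
N the unsampled population size of the relevant sex.  N_males and
N_females carry broad lognormal priors (μ = log 7 and log 2, σ = 0.5)
and are updated by random-walk Metropolis-Hastings on the log scale,
step size tuned during burn-in to a 30–50% acceptance window.  Pairs
that would make the offspring its own ancestor are masked out of the
conditional — the exact Gibbs step on the legality-constrained
posterior, so the pedigree is legal at every iteration.  Chains are
thinned every 2 iterations; every stochastic routine takes an explicit
seed and reruns are bit-identical.

Offspring are visited in reverse detection-date order and, by default
(`require_prior_detection`), candidate parents must have been first
observed before the offspring — the operational form of ordering the
data so that later-observed individuals are fitted as offspring of
earlier-observed ones.  Sweep order alone cannot achieve this (it does
not change the stationary distribution); the candidate restriction
does, and it resolves most parent-offspring direction ambiguity
without requiring age data.

On small instances (≤ 3 offspring, ≤ 3 candidates per role) the
sampler's posterior pair frequencies are verified against brute-force
enumeration of all legal configurations.

### Error-rate estimation

With the pedigree fixed, per-locus (E1, E2) are sampled by
Metropolis-Hastings on the logit scale under Beta(4, 100) and
Beta(2, 100) priors, initialised at 0.1.  All replicates of all
samples of an individual share one latent true genotype; its prior is
Hardy-Weinberg, or Mendelian transmission from the parents' consensus
genotypes where the fixed pedigree provides confident parents.  Repeat
-sample concordance and family structure therefore both inform the
posterior.  Loci without informative replicates return the prior and
are flagged.  At 2-allele loci dropout and miscall are nearly
confounded (both convert heterozygotes to homozygotes); homozygous
individuals identify E2, which is why recovery is tested on the
multi-allele panel.

## The staged estimation protocol

1. **Preliminary pedigree** — one chain at fixed (E1, E2) =
   (0.04, 0.022), 20 000 iterations, burn-in 2 000; links above 90%
   confidence form the input pedigree for error estimation.
2. **Error rates** — per-locus posteriors as above, for scat samples.
3. **Possible breeders** — 20 chains of 25 000 iterations (burn-in
   1 000); an individual qualifies when it averages ≥ 1 modal
   parentage assignment per run.  The screen is repeated once with
   candidates restricted to the first-pass set and a stricter bar
   (≥ 1.5), which forces impostor relatives to compete directly with
   the true parents and empirically removes most of them.  A
   fraction-of-parentage-slots rule (≥ 5% pooled or per run) is
   available via config, but note it deterministically excludes every
   breeder with fewer offspring than 5% of slots, regardless of how
   consistently it is assigned.
4. **Main fit** — 20 chains of 30 000 iterations (burn-in 3 000) with
   candidates restricted to the possible breeders.
5. **Averaging** — per offspring, each pair observed in any run's
   modal pedigree gets the mean of its per-run posterior support
   (absent in a run = 0; the mean-over-present-runs variant is a
   config option); the maximum-mean pair wins, ties toward UNSAMPLED.
   Per-slot confidence is the mean *marginal* support of the winning
   dam and sire separately: assignments are reported per parent, and a
   parent that is certain should not be down-weighted because its mate
   is split between candidates.
6. **Consistency** — flags temporally impossible links (minimum
   breeding age 2 under birth years inferred from sibling-group
   detections), medium-confidence (70–80%) pairs with a single
   assigned offspring, and two litters in one territory-year; reports
   the both/only-mother/only-father/neither counts at the confident
   (> 80%) threshold.  Corrections are applied only through an
   explicit, validated ledger (reason codes ANACHRONISM,
   SINGLE_OFFSPRING_PAIR, TERRITORY_CONFLICT, CONFIRMED); an edit that
   would create a cycle is rejected.

Confidence vocabulary: confident > 0.80, high > 0.90, very high
> 0.95, medium 0.70–0.80.

### Chain lengths used in the packaged experiments

The defaults above are the full production settings.  The packaged
tests and the acceptance script use `ProtocolConfig.desk_scale()` —
step 1: 4 000/800; step 2: 1 500/400; step 3: 6 × 2 500/400; step 4:
12 × 3 000/500 — which this package adopts as its standard experiment
size: on the ~75-individual fixture the chains mix well within these
lengths (posterior pair frequencies are stable across seeds) and a
full protocol run takes a few minutes.  All scientific constants
(error-rate constants, priors, thresholds, exclusion rules) are
identical between the two configurations.

## Pedigree statistics

Kinship uses the standard recursion φ(x,x) = (1+F_x)/2,
φ(a,b) = (φ(dam_a,b)+φ(sire_a,b))/2 with memoisation; UNSAMPLED and
UNKNOWN parents are unrelated founders (each offspring's unsampled
parent is a distinct anonymous founder; a merge helper exists for
manually linking a shared unsampled pair).  The additive-relationship
(tabular) method is kept as an internal oracle and the two paths are
tested for equality on random pedigrees.  F of an individual is the
kinship of its parents; relatedness r = 2φ/√((1+F_a)(1+F_b)).
The population-level allele-frequency inbreeding estimate is a
per-individual maximum likelihood fit of
P(hom) = p²(1−F) + pF, P(het) = 2pq(1−F) on F ∈ [0,1]
(bounded 1-D optimisation, tolerance 1e-6); it measures departure from
Hardy-Weinberg, so in a population of large sibling groups it runs far
above the pedigree-based F — the two statistics answer different
questions and are both exposed.

Birth years are inferred per sibling group (same assigned parent
pair): the earliest year consistent with every member's first
detection and each sampled parent reaching breeding age, with parents'
own birth years falling back to their first-detection year.  Wolf
litters are annual, so cohorts are calendar years; conflicting
constraints are flagged, not fatal.

## Synthetic populations

The generator emulates the study system's structure: `n_packs = 4`
territories over `years = 7` breeding seasons; each territory is held
by a single breeding pair producing at most one litter per year
(Poisson, mean 4); breeders die at 0.15/year; vacancies are refilled
by inheritance of the breeding position (p = 0.3), female-biased local
dispersal (p = 0.3) or male-biased immigration (p = 0.5), immigrants
arriving with UNSAMPLED parents at age 2–4; minimum breeding age is 2
and parent-offspring pairings are banned.  These defaults are chosen
to reproduce the scale of a small re-establishing population —
roughly 80 individuals and 7–8 breeding pairs — not estimated from
any particular dataset.

Sampling: each individual-year alive is detected with probability
0.7; a detected individual yields 1 + NegBin(mean 3, shape 3) samples
(median ≈ 4 per individual), 93% scats, dated within detected years
and scattered (Gaussian, σ = 8 km) around the pack centre; every
sample is genotyped in triplicate per locus with 5% per-replicate
failure, with a second triplicate where the consensus rule demands it.

Allele frequencies: 17 loci with 2–9 alleles, Dirichlet-drawn and
rejection-matched to per-locus heterozygosity targets spread over
[0.20, 0.80] and tilted so the panel mean lands at 0.58 ± 0.03.

What the generator does **not** emulate: spatially explicit dispersal
and territory overlap (coordinates are decorative), within-year litter
timing, null alleles/stutter/contamination, immigrant source-population
structure (immigrant genotypes come from the same frequency table),
dogs and hybrids, and uneven collection effort across years or
collectors.  Detection also begins in an individual's birth year,
which makes first-detection dates unusually informative about birth
order; real monitoring starts mid-history and detects individuals
late, so the detection-order candidate restriction is safer here than
it would be on real data (on the fixture, no true parent is first
detected after its offspring; on real data the restriction can be
disabled).  Passing recovery tests on this fixture therefore
demonstrates the machinery under the stated error and sampling
conditions, not performance on any real population.

## Recovery behaviour and known limitations

On the packaged fixture (75 individuals of which 68 are sampled, 17
loci, panel H_E ≈ 0.58, E1 = 0.04, E2 = 0.022), protocol steps 1–5
confidently and correctly assign ~91% of the 2N parent slots.  The
small number of *confident but wrong* assignments (~3% of confident
slots; 3–5% across seeds and fixture variants) are full siblings or
second-generation breeders fitted as parents.  This is a property of the factorised pedigree model, not of
the sampler: among the many relative pairs of an offspring, the
best-matching pair can have a genuinely higher Mendelian likelihood
than the true parents (verified with true genotypes at zero error),
and without age data the model has no information to refuse them.
These are exactly the assignments the consistency stage (step 6)
flags as temporally impossible or single-offspring pairs for
ledger-based correction; a fit given true cohorts removes them via the
exclusion filter.  Users should treat step-5 output as provisional
until step-6 flags are reviewed.

The panel-power experiment probes the accuracy of an existing fit:
genotypes are resimulated on the fitted pedigree with the same
frequencies, error rates and possible-parent set, and refit with
steps 4–5 (steps 3–5 when no breeder set is supplied).  Because the
supplied breeder set already excludes too-young impostors, false
positives among confident assignments are near zero there — the gap
between that design and from-scratch estimation is worth keeping in
mind when quoting either number.  Panels larger than the real 17 loci
duplicate markers as independent loci sharing the source locus'
frequencies, the only reading under which duplication adds
information.

## Numerical choices

* Genotype-state spaces are enumerated per locus (k(k+1)/2 unordered
  pairs); all error/transmission algebra is dense matrix arithmetic.
* Log-likelihood −∞ (Mendelian exclusion at zero error) is handled by
  masking, never by epsilon-flooring the likelihood itself; the
  UNSAMPLED pair always has positive posterior mass, so conditionals
  are always proper.
* Ties in modal/averaged pairs break toward UNSAMPLED (conservative:
  prefer no link over a doubtful link), then lexicographically.
* Should modal pairs jointly form a cycle, offspring are re-assigned
  greedily in decreasing order of support, each taking its most
  probable pair that keeps the configuration acyclic; the result is
  flagged `REPAIRED`.
* Step-size tuning for all random-walk updates runs only during
  burn-in (windows of 50 iterations, multiplicative adaptation), so
  the post-burn-in chain is a fixed-kernel Markov chain.
* Frequency-table rejection sampling falls back to a deterministic
  uniform/point-mass mixture (bisection on the mixing weight) if 3 000
  Dirichlet draws miss the per-locus heterozygosity target.
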