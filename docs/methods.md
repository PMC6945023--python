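# Methods

## Model

The unit of modelling is the coalescent level: with *n* sampled
haploid genomes, level *k* (k = n … 2) is the stretch of a genealogy
during which exactly *k* ancestral lineages persist, and each level is
assigned its own diploid effective size N_k. Waiting times at level k
are exponential with mean 4N_k/[k(k−1)] generations, so a demographic
history is a vector of n−1 sizes and population-size change happens,
by construction, at the (expected) coalescence times. This is a
deliberately granular approximation of continuous size change: with
growing *n* the grid of levels refines, and bootstrap averaging
smooths the steps further.

The branch-position probabilities of an allele of frequency class r
(which levels its branch can start and end at) depend only on *n* and
*r*, never on the sizes; only branch *lengths* depend on the N_k.
That separation gives every expectation used here the same shape — a
topology-determined weight times a size-dependent duration:

* expected SFS: E[G_r] = (4uL/r) Σ_k w(n,r,k) N_k with
  w(n,r,k) = C(n−k, r−1)/C(n−1, r); the weights for fixed r sum to
  one (hockey-stick identity), so constant N recovers 4NuL/r and the
  singleton class measures the arithmetic mean of N_2…N_n.
* allele-age moments: mean and second moment of the age of an order-r
  SNP are ratios of sums over the possible starting levels k, weighted
  by N_k·C(n−k, r−1), of the expected time (and squared time) from k
  to the root.
* experienced Ne: E[P_r] = E[∫₀^A N(s) ds]/E[A_r], a ratio of
  expectations (not an expectation of ratios), reduces to a weighted
  average of the N_k and therefore always lies in [min N_k, max N_k].

A second, independent derivation route for the expected SFS goes
through the expected number of order-r branch segments alive while k
lineages remain (k·C(n−r−1, k−2)/C(n−1, k−1), the classic Kingman
branch-count result): each segment starting at level k carries a
mutation with probability 4u·mean(N_2…N_k)/k. `expected_sfs_via_W`
implements this route purely as a cross-check; the two paths agree to
floating-point rounding and the property suite enforces 1e−9 relative
agreement.

θ = 4N_k·u (diploid) throughout; a `haploid` flag in the expectation
API halves the factor.

## Estimation

The observed classes G_1…G_{n−1} are treated as independent Poisson
variables with the means above (composite likelihood; log-factorial
constants dropped). The monomorphic class is excluded by default —
its expectation is not needed once L enters the polymorphic means —
but an `include_monomorphic` switch adds a Poisson term for
G_0 = L − ΣG_r for sensitivity analysis. Excluded classes (e.g.
error-prone singletons) are retained in the data structure and skipped
only inside likelihood sums, so folding and bootstrapping stay
well-defined.

A model is a set of breakpoints partitioning the levels into
contiguous groups, one free size per group (breakpoint b separates
levels i > b from i ≤ b). Because the means are linear in the group
sizes, the log-likelihood is concave in them; maximisation runs on
log sizes (positivity for free): L-BFGS-B with the analytic gradient,
then exact-Hessian Newton polishing until the projected-gradient norm
falls below 1e−8·|ℓ|, otherwise the fit is flagged non-converged
(never silently returned; non-converged bootstrap replicates are
dropped and counted). Sizes start at the Watterson estimate and are
bounded below at 1e−6 times it. With zero breakpoints the maximiser
is Watterson's estimator analytically, which the tests verify to
1e−8.

The stepwise search starts from the constant-size model and adds one
breakpoint per iteration, accepting the best candidate only if the
log-likelihood gain is at least the threshold (default 2.0 — the AIC
penalty of one extra parameter at the conventional "improves by 2"
reading; configurable). Greedy mode keeps previously accepted
breakpoints and tries each unused level, always re-optimising all
group sizes jointly; exhaustive mode re-evaluates every combination
of the new cardinality. Equal-likelihood candidates (within 1e−9)
tie-break to the smallest, i.e. most ancient, level, making the
search fully deterministic. Candidate levels are {2…n−1} for folded
and unfolded spectra alike; for folded data identifiability is left
to the stopping rule, which is exactly what level pooling is for.

Fitted histories are reported as step functions: step k starts at
τ_b = Σ_{j>b} 4N̂_j/[j(j−1)], the expected start of the level-b
interval under the fitted sizes. Times are in generations;
calendar-year conversion is left to the user. (For *Daphnia*-style
data a mutation rate of u = 5.7e−9 per site per generation is a
typical input.)

## Synthetic data and what it does not emulate

The simulator draws Kingman genealogies in either of two modes:
level-indexed (exponential waits with mean 4N_k/[k(k−1)] — exactly
the inference model, used for oracle tests) and time-indexed
(piecewise-constant N(t) epochs, pairwise rate k(k−1)/(4N(t))
integrated across epoch boundaries — the shape of standard ms-style
validation scenarios, used for recovery experiments where model and
truth deliberately differ). Mutations follow infinite sites: counts
are Poisson in u·L·branch length, drawn per class from aggregated
class lengths (exact and O(branches), never O(L)); positions along a
branch are uniform, which is what makes the n=2 closed form
E[A_1] = 2N hold. Mutation records carry the realized age and the
exact ∫N(s)ds over the mutation's lifetime, clustered by genealogy;
summaries use cluster-robust (ratio-estimator) standard errors
because mutations sharing a tree are correlated.

`simulate_sfs` can split the L sites over `num_genealogies`
independent trees. Real spectra aggregate loosely linked loci, so a
single shared genealogy would carry far more between-class
correlation than genuine data; the recovery experiments use 2,000 to
5,000 blocks so that Poisson noise (which the composite likelihood
and the site-level bootstrap can see) dominates genealogy noise
(which they cannot). The generator has no recombination within
blocks, no selection, no population structure and no sequencing
error, so passing recovery tests demonstrate correctness of the
estimator under its own assumptions, not robustness to their
violation.

Named scenario presets (constant, two-epoch decline/expansion,
bottleneck) are this package's own fixtures: a 10,000-individual
baseline with tenfold size changes at 500/1,500 generations — sizes
and times chosen so that, at n = 20, both epochs straddle the levels
the sample can resolve.

## Numerical choices

* All binomial coefficients via log-gamma, exponentiated only after
  subtracting a common normalisation; n in the hundreds is safe
  (samples of ~186 genomes are realistic for low-coverage population
  data).
* Inner sums over deeper levels (Σ_{ℓ≥k} N_ℓ/[ℓ(ℓ−1)] and its square)
  are suffix cumulative arrays: O(n) per frequency class.
* The bootstrap resamples sites multinomially over classes including
  the monomorphic class, conserving L exactly; it cannot, by
  construction, resample genealogies.
* Bootstrap/aggregation time grids are logarithmic between the 1st
  and 99th percentiles of the pooled step times (200 points,
  configurable); step functions are right-continuous and extend
  flat beyond both ends.
* Degenerate inputs: S = 0 gives Watterson Ne = 0 and the fitter
  falls back to its size floor; zero-count classes contribute only
  −μ_r and are harmless; a mutation mean of zero with a positive
  count yields −∞ likelihood, flagged rather than masked.

## Problem sizes used in the checks

The oracle comparisons run 1e5 genealogies per configuration
(n ∈ {2, 4, 8, 20}), the allele-age and experienced-Ne oracles 4e4
and 5e4 genealogies at low mutation pressure (≈0.4 mutations per
tree) so records stay nearly independent, and the decline-recovery
experiment uses n = 20, 1e7 sites over 5,000 blocks with 200
bootstrap replicates — sizes at which Monte-Carlo standard errors
are a few percent and each check completes in minutes on one CPU.

## Known limitations

* The composite likelihood ignores linkage between SNPs; with few
  independent blocks the bootstrap bands are anti-conservative.
* Deep-time resolution degrades intrinsically: few polymorphisms
  survive beyond ~4Ne generations, and the last levels pool large
  spans of time. Very recent changes are likewise invisible below
  the timescale of the first coalescence events at the sample size
  at hand.
* The exhaustive search cost grows combinatorially with the number
  of accepted breakpoints; the greedy mode is the practical default.
* Folded spectra halve the number of observed classes while the
  parameter count stays n−1; expect the stopping rule to select
  fewer breakpoints than with polarised data.
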