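# Methods

This note documents the statistical procedures implemented in `kelpcoast`,
the assumptions behind them, the defaults of the synthetic-coast generator,
and the numerical choices that matter for reproducibility.

## Distances

All sequence comparisons exclude alignment columns where either sequence
carries a gap or a non-ACGT ambiguity code; this is the conservative
convention for clean Sanger haplotype data and means a column bad in one
haplotype is dropped from that *pair's* comparison only (and from
variable-site summaries entirely when any haplotype is ambiguous there).

* **Raw differences** d(i, j): count of differing comparable sites.
* **p-distance**: d / (number of comparable sites); no multiple-hit
  correction. Percentages are reported rounded half-up to one decimal.
* **Nei's raw average pairwise difference** between populations A and B:
  D = (1/n_A n_B) Σ_{i∈A} Σ_{j∈B} d(i, j), over *sample* pairs. Collapsing
  each population to haplotype frequencies and weighting gives the identical
  value, which is how the implementation computes it. D is deliberately left
  on the raw count scale (not divided by length, not corrected): the
  disjunction rule "D ≥ 1.0" means "on average at least one whole fixed
  difference per cross-population sample pair" and is meaningless on any
  other scale.
* **Within-population π**: mean d over distinct unordered pairs (i < j),
  denominator n(n−1)/2; a single-sample population has π = 0.
* **Pairwise F_ST**: (π_between − π̄_within)/π_between with π̄_within the
  unweighted mean of the two within-population values, clamped to [0, 1].
  When π_between = 0 the quantity is undefined and reported as such (None),
  rather than 0: two populations fixed for the *same* haplotype carry no
  information about differentiation. Two populations fixed for *different*
  haplotypes give F_ST = 1 whatever the haplotype distance — which is
  exactly why the Mantel analysis uses D, not linearised F_ST.

Coastal distances are |x_i − x_j| over user-supplied cumulative coastal
positions; the package validates that positions are monotone in the declared
coastal order but treats the positions themselves as authoritative input
(measuring around bays is the user's concern, not the library's).

## Mantel isolation-by-distance test

Pearson correlation r between the strict upper triangles of the genetic-D
and coastal-distance matrices. The null distribution permutes rows and
columns of the genetic matrix jointly (the geographic matrix stays fixed);
the test is one-tailed (upper), matching the directional IBD hypothesis, and
uses the +1-corrected estimator p = (1 + #{r_perm ≥ r_obs})/(1 + N), which
counts the observed labelling among the permutations and is never zero.
Permutations are drawn from a seeded generator; results are bit-for-bit
reproducible given (seed, N). Ties are compared with a 1e-12 tolerance so
that symmetric configurations count as ties rather than falling to floating
point noise. Matrices must share labels in the same order; zero-variance
matrices are rejected as degenerate.

## Statistical-parsimony connection limit

The network stage needs the largest number of mutational steps j, for a
fragment of L sites, at which a connection between two haplotypes differing
at j sites is still "parsimonious" (no superimposed, invisible changes) with
probability at least the chosen confidence c (0.95 classically; 0.90 for the
more permissive join used in the two-clade analysis).

The package computes this as an explicit posterior under a symmetric
(Jukes–Cantor) finite-sites model:

1. Mutations land uniformly on the L sites. A site hit k times ends up
   visibly different from its original base with probability
   v(k) = (3/4)(1 − (−1/3)^k) (so v(1) = 1, v(2) = 2/3, ...).
2. P(j visible | u mutations) follows exactly from coincident-hit
   combinatorics; it is evaluated via exponential generating functions
   (one factor Σ v(k) x^k/k! per visible site, Σ (1−v(k)) x^k/k! per
   invisible hit site), with exact integer combinatorial factors.
3. The unknown true number of mutations u ≥ j gets a Poisson prior whose
   mean is the Jukes–Cantor-corrected expected number of substitutions for
   the observed divergence, θ = −(3/4) L ln(1 − 4j/3L).
4. The probability of parsimony is the posterior P(u = j | j observed),
   with the sum over u truncated at u = j + 6: each additional superimposed
   mutation contributes roughly a factor θj/(3L) < 1/3 anywhere near the
   limit, so the truncated tail is far below the decision tolerance.

The connection limit is the largest j with posterior ≥ c. The test suite
verifies this computation against an independently coded oracle that
evaluates step 2 by brute-force enumeration over integer partitions of u
(exact rationals), for L ∈ {100, ..., 1000} × c ∈ {0.90, 0.95}; the two
routes agree exactly. Resulting limits (e.g. 11 steps at 629 bp / 90%,
7 at 95%) are monotone in both L and 1 − c and separate the deep between-
clade divergence of the kelp system (≥ ~28 steps) from the shallow
within-clade divergence (≤ ~8 steps) with a wide margin.

## Network assembly

Haplotype pairs are processed in order of increasing raw distance (ties:
higher combined frequency first, then lexicographic IDs — making assembly
deterministic and input-order invariant). A pair at distance d ≤ limit whose
haplotypes lie in different components is joined through d − 1 hypothetical
intermediate nodes (named x1, x2, ... in creation order; their sequences are
not imputed because nothing downstream uses them). A pair whose components
are already connected contributes no edge; when the direct connection would
tie the existing graph distance, it is recorded as an ambiguous alternative
link. Pairs beyond the limit never connect. This greedy scheme deliberately
simplifies the original program's probabilistic intermediate placement and
loop retention: component membership — the only network property the
downstream analysis consumes — depends only on pairwise distances versus the
limit (it equals the transitive closure of "d ≤ limit", which the test suite
checks against an exhaustive oracle). Forced display-only joins between
components are never emitted.

## Disjunction classification and Firth regression

Adjacent locality pairs (consecutive in coastal order, optionally within a
region filter; excluding an interior locality re-pairs its neighbours) are
classified **disjunct** iff Nei's D ≥ threshold, default 1.0, inclusive.
Haplotype sharing is computed independently from the count matrix and any
pair that is disjunct *and* shares haplotypes is flagged in a consistency
report — the two operational definitions coincided in the motivating system,
and the report makes a divergence between them visible rather than silent.
Classification is monotone in the threshold.

The regression is `disjunct ~ max_beach_km + coastal_km` with Firth's
penalty ℓ*(β) = ℓ(β) + ½ log det(XᵀWX). With ~15 observations and barriers
that separate the response almost perfectly, the unpenalized MLE diverges;
the Jeffreys-prior penalty keeps all estimates finite (an intercept-only fit
to constant y has the closed form p̂ = (Σy + ½)/(n + 1), which the tests use
as an oracle). Estimation is modified-score Newton iteration
(U*_r = Σ_i (y_i − p_i + h_i(½ − p_i)) x_ir) with step-halving whenever the
penalized likelihood would decrease; convergence at max |U*| < 1e-8 within
50 iterations, non-convergence flagged but estimates still returned.
P-values are penalized likelihood-ratio tests: each term is fixed at zero
and the others re-estimated under the full-design penalty (profile fit);
2Δℓ* is referred to χ²₁. Wald standard errors from the inverse information
accompany them. Coefficients transform exactly under affine predictor
rescaling (km → m divides β by 1000), verified in tests. The grid-search
oracle agrees with the Newton optimum to 1e-4 on a fixed 8-observation
dataset, and on large well-separated samples the estimates approach the
unpenalized MLE (cross-checked against statsmodels) at the expected O(1/n)
rate.

## Synthetic coast generator

The generator is a forward haplotype-pool model, not a coalescent simulator:
the analyses consume only haplotype frequencies and pairwise distances, so a
minimal model that plants the target signals is fully controllable and
sufficient. Defaults mirror the motivating study's scale: a 629 bp marker,
16 northern + 5 southern localities ~90 km apart (gaps jittered ±15% so
coastal distance is a non-degenerate predictor), 8 samples per locality,
between-clade divergence 0.05 (drawn Binomial(L, 0.05), mean ≈ 31.45 steps
at the defaults), transition:transversion weight 9:1.

* **South**: every sample is the same haplotype, a binomial number of steps
  from the northern founder — monomorphism emulating postglacial
  recolonisation by one rafted lineage.
* **North**: haplotypes form a mutational chain (one fresh site per step, so
  chain distance is exact). Each locality carries a continuous drift
  coordinate t; samples draw chain index ⌊t⌋ or ⌊t⌋+1 according to the
  fractional part. Between adjacent non-barrier localities, with probability
  `ibd_step_prob` (default 0.5) t advances by Uniform(0.2, 0.8): the new
  haplotype enters at intermediate frequency, neighbours keep sharing
  haplotypes, and the expected adjacent D stays below 1 (a model in which
  the pool advances a whole step per event provably has E[D] ≥ 1 for every
  stepped pair, i.e. plants false disjunctions). Cumulative smooth drift is
  capped at `max_within_clade_steps` (default 8, the within-clade divergence
  scale of the motivating system); barrier jumps add beyond the cap, since a
  strict cap on total within-clade distance is incompatible with several
  disjoint barrier pools on one chain.
* **Barriers**: beach lengths are a mixture (long Uniform(25, 70) km with
  probability 0.3, else short Uniform(0, 15) km). A beach over 20 km advances
  t by exactly 2 whole steps, which makes the two pools' chain supports
  provably disjoint and every cross-pair distance ≥ 1 — hence D ≥ 1 and the
  planted disjunction is recovered deterministically, not stochastically.

Identical seeds give byte-identical output files. The truth JSON records the
planted clade membership, barrier pairs and drift coordinates for recovery
tests.

What the generator does **not** emulate: within-locality coalescent
genealogies, recombination, selection, explicit rafting dynamics, unequal
sample sizes, sequencing error or ambiguity codes. Passing recovery tests
therefore demonstrates that the pipeline detects clean planted signals of
realistic magnitude — not that it is robust to messy field data.

## Problem sizes and determinism

Recovery tests run 200 seeded replicates of the full pipeline
(21 localities × 8 samples, 999 Mantel permutations each); Mantel type-I
calibration uses 1000 null matrices at 199 permutations, where the +1
correction makes the attainable rejection level 9/200 = 4.5%, and the
observed rate is required to sit in the binomial 99% interval around it.
Every stochastic component takes an explicit integer seed
(`numpy.random.default_rng`); pipeline reports contain no timestamps so
reruns are byte-identical.

## Known limitations

* The connection-limit posterior is one defensible operationalization of
  statistical parsimony; other implementations make slightly different
  approximations and may differ by a step or two at a given length. The
  analyses here depend only on the limit falling between the within- and
  between-clade divergence scales, which holds with a wide margin.
* F_ST uses the simple π-based estimator; no AMOVA, no linearised
  F_ST/(1 − F_ST), no model-corrected distances (TrN, K2P) — all out of
  scope by design.
* Coastal positions and beach lengths are taken as given; the package does
  not measure geography.
* With very small populations per locality, D and the disjunction
  classification are noisy; the threshold semantics (inclusive ≥) matter at
  the boundary.
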