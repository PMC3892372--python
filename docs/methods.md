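# Methods

## The clonal mixed model and its sampler

The core model treats each clonal family as one genotype replicated
whole-genome: for trait vector y<sub>ij</sub> (replicate *j* of clone *i*)

    y_ij = mu + g_i + e_ij,   g_i ~ MVN(0, G),   e_ij ~ MVN(0, E).

The among-clone covariance G is *broad-sense*: it contains additive,
dominance and epistatic variance alike, which is the relevant quantity for
parthenogenetic lineages where the whole genotype is transmitted. No
pedigree/animal model is offered — the design has no relatedness structure
beyond clone identity.

Inference is a Gibbs sampler with conjugate full conditionals: clone
effects and the mean are multivariate normal (the mean under a flat
prior), G and E inverse-Wishart. Updates are vectorized across clones by
grouping families with equal replicate counts, so one iteration costs a
handful of p×p factorizations regardless of sample size; inverse-Wishart
draws use the Bartlett construction. Near-singular conditional precisions
get a logged ridge (1e-8 × mean diagonal) before factorization.

**Parameter expansion** (default on): the model is re-written as
y = mu + Dα u_i + e with Dα = diag(α), u_i ~ MVN(0, V) and G = Dα V Dα.
The working scales α (one per trait, normal prior N(0, 625 I)) have a
Gaussian full conditional and are folded into G at every stored sample.
This is the standard cure for the sticky behaviour of variance components
near zero under weak inverse-Wishart priors. With expansion off the
sampler reduces to the plain conjugate scheme, which is the configuration
used when checking against the exact conjugate oracle (the expanded prior
on G is no longer inverse-Wishart, so exact prior correspondence requires
expansion off).

**Priors.** Default ν<sub>g</sub> = ν<sub>e</sub> = p + 1 and scale
0.01 I — proper but weak on standardized traits. All prior hyperparameters
are plain config fields; nothing is hard-coded.

**Chain lengths.** Two named profiles: `paper` (500 000 burn-in, 1 000
samples stored from 100 000 further iterations, thin 100) for final runs,
and `test` (5 000 / 5 000 / 500) for routine work. The test suite and the
acceptance script use the test profile throughout; at the simulated sample
sizes (9–100 clones) its effective sample sizes are in the hundreds, which
the `chain_diagnostics` helper (autocorrelation-based ESS via arviz)
verifies.

**Zone effects.** An optional per-trait, zero-mean random intercept for
geographic zone (independent variances per trait, scaled-inverse-χ²
updates). Off by default: in the motivating design the zone variance
components were indistinguishable from zero, and the bundled study
simulates no zone shifts.

**Summaries.** Point estimates are modes of a Gaussian KDE (Silverman
bandwidth, 512-point grid over the sample range); intervals are
highest-posterior-density: the shortest window containing ⌈0.95 n⌉ sorted
samples. Heritabilities and genetic correlations are computed per
posterior sample and then summarized — never as ratios of summary
statistics. Element-wise mode matrices need not be PSD; reported G modes
are projected to the nearest PSD matrix (negative eigenvalues clipped)
with the adjustment logged.

## Comparison metrics

All four pairwise statistics are computed per posterior draw, pairing
draws by sample index (the chains are independent, so any fixed pairing is
valid; index pairing keeps reruns reproducible).

* **Ovaskainen's D** has no closed published formula in the source
  tradition this package follows; it is implemented operationally as
  D = 2 max(0, P − ½), where P is the probability that the Frobenius
  distance between one draw from each posterior exceeds the distance
  between two distinct draws of one (randomly chosen) posterior.
  Identical posteriors give P ≈ ½ (D ≈ 0); posteriors with disjoint
  support give P ≈ 1 (D ≈ 1). The definition lives in a single function
  (`gcompare.ovaskainen_d`) so it can be swapped without touching callers.
  Its interval is a bootstrap over the Monte-Carlo draw pairs, and its
  significance is judged against a permutation null (pooled draws split at
  random, 100 permutations).
* **Krzanowski angle** between Gmax axes is arccos of the absolute dot
  product, restricted to [0°, 90°]. An HPD for an angle cannot reach 0 by
  construction, so significance uses a permutation null of the pooled
  draws (500 permutations, medians compared at the 95th percentile).
* **Δ variance of Gmax** and **Δ total variance** are plain per-draw
  differences (convention: first argument minus second); significant when
  the 95% HPD excludes zero.

Gmax sign is fixed by making the largest-magnitude loading positive; exact
eigenvalue ties (within 1e-12) are broken toward the lowest trait index
with a warning — the direction is genuinely undefined there.

## Covariance tensor across a gradient

Symmetric matrices are vectorized with off-diagonals scaled by √2, making
the Euclidean inner product equal the Frobenius inner product. The sample
covariance S (denominator m − 1) of the m vectorized G-matrices is the
matrix representation of the fourth-order covariance tensor; eigenanalysis
of S gives at most m − 1 eigentensors with nonzero variance.

Per posterior draw, the m G draws are decomposed and matched to a
reference decomposition (from the element-wise posterior-mean matrices) by
maximal |Frobenius overlap|, which resolves label switching; draws whose
best match falls below 0.5 overlap are counted (`n_unmatched`).
Proportions are renormalized over the retained m − 1 axes per draw, so
their modes sum to ~1 but not exactly (modes of simplex components).

Two sign conventions are needed and both are explicit in the code:
the leading eigentensor is oriented so its projection onto
(G<sub>first</sub> − G<sub>last</sub>) along the stated gradient order is
non-negative — it then reads as *change seen moving against the gradient*,
so a population order running from the most-derived to the ancestral end
makes "loss of variance toward the derived end" a negative loading. The
per-trait loadings are the leading eigentensor's dominant eigenvector
multiplied by the sign of its eigenvalue. Site variances are the Rayleigh
quotients vᵀG<sub>j</sub>v of that (unit) eigenvector and are
sign-invariant.

No sampling-error correction of S is applied; the decomposition describes
the posterior draws as they are.

## Means and selection analyses

Family-mean contrasts use a one-way linear model with all pairwise
contrasts adjusted by the studentized-range distribution with the
Tukey–Kramer allowance for unequal group sizes (equivalent to Tukey HSD
when balanced; cross-checked against statsmodels). Traits are z-scored
with the sample SD (ddof = 1); both a global scope (used for cross-region
contrasts, so differences read as SDs of the pooled study) and a
per-population scope are exposed, since either choice is defensible and
they answer slightly different questions.

Selection gradients regress relative fitness w = r_m / mean(r_m) on
within-population standardized body mass and size at birth. Forward
stepwise selection offers the two linear terms first (best partial F
first); quadratic and correlational terms become candidates only once
their linear parent(s) are already in the model, and the stepwise loop
keeps unselected linear terms on offer afterwards. Each step admits the
candidate with the smallest partial-F p-value below α (default 0.05).
Quadratic gradients are reported as **twice** the fitted quadratic
coefficient so that γ measures the curvature of the fitness surface; the
cross-product coefficient is itself the correlational gradient. A direct
consequence of the marginality gate: *pure* stabilizing selection with no
linear component cannot enter the model — the gate is what keeps the null
family-wise error near the two-linear-candidate level (~10% at α = 0.05)
rather than the ~15–20% of an ungated five-candidate scan, and that
trade-off is deliberate. Analyses default to individual replicate records;
a family-mean mode is available behind a flag.

## Synthetic data: what it emulates and what it does not

The generator draws clone effects from MVN(0, G_true) and residuals from
MVN(0, E_true), i.e. it matches the inference model exactly apart from two
deliberate real-world touches: AFR is floored at half a day and reported
at 0.1-day resolution (the model remains effectively exact; a censused
integer day would not be), and offspring number is Poisson with values
below 1 resampled so ln(ON) is defined. Fitness surfaces are generated on
within-population z-scores and recentered so mean(w) = 1 exactly, which
makes the recorded gradients the true gradients of relative fitness.

Consequently, passing tests demonstrate correct *inference under the
model*: they do not probe robustness to non-Gaussian phenotypes,
genotype–environment interaction, measurement error correlated with
genotype, or missing-data patterns, none of which the generator produces.
The bundled study fixes the design at 30/14/9 clonal families — the
motivating study's family counts — with 5 replicates per family (the
underlying breeding design implies up to ten sublines per genotype but no
per-genotype replicate count is fixed by it; 5 is the package default and
a config key).

Each population gets its own RNG stream keyed by (master seed, population
index), so adding a population never perturbs earlier draws; every
pipeline stage derives a named substream from the master seed (CRC-based
tag, stable across processes), which is what makes the end-to-end summary
byte-reproducible.

## Numerical choices and degenerate inputs

* Covariance inputs are validated to symmetry (1e-10) and eigenvalues
  ≥ −1e-10; MVN draws use an eigendecomposition root so rank-deficient
  (including all-zero) covariances are legal.
* KDE modes fall back to the constant for zero-range samples; HPD of a
  point mass is a zero-width interval.
* Posterior samples with zero total variance for any trait are excluded
  from H²/r<sub>g</sub> summaries with a logged count.
* An all-zero S tensor yields an empty decomposition with a warning
  rather than NaNs.
* Fewer clones than traits triggers a RuntimeWarning (posterior will be
  prior-dominated) but is allowed, matching the smallest real design
  (9 families, 3 traits).

## Known limitations

* Broad-sense only; no additive decomposition, no pedigree.
* The D metric is an operational stand-in with the documented
  classification semantics; alternative published formulations would slot
  into the same function but are not implemented.
* Significance of the angle and of D rests on permutation nulls over
  posterior draws — a pragmatic, seeded convention, not a frequentist
  guarantee.
* The stepwise scan considers at most five terms (two traits); it is not
  a general model-selection engine.
* Chains are single-run; convergence is assessed by ESS, not by
  multi-chain R-hat.
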