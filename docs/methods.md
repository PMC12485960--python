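# Methods

## The colonization model

The package models the occupancy state of an ephemeral resource patch as
the outcome of a compound Poisson process. Colonization events arrive
independently at rate λ_C per patch lifetime (Poisson-distributed count C),
and each event delivers a founder group whose size D is Poisson(λ_D)
conditioned on being nonzero (zero-truncated: a colonization by definition
delivers at least one dauer). All patches are assumed equivalent in quality
and accessibility, and the process is independent across patches and across
species. Proliferation after founding is fast and large, so identified worm
counts from a proliferated patch carry no information about founder numbers;
the informative observations are (i) whether a patch is empty and (ii)
whether an occupied patch holds exactly one worm, which for an obligately
outcrossing species implies a single colonization that delivered a single
dauer (a lone founder cannot have reproduced).

Inference:

* **λ_C from emptiness.** k of n patches empty → binomial likelihood with
  success probability e^(−λ_C); MLE −ln(k/n). When only an occupancy
  percentage is available, `rate_from_occupancy_fraction` applies
  −ln(1 − fraction) directly.
* **λ_D conditional on λ_C.** n_single of n_occupied patches single-worm →
  binomial likelihood with success probability
  p = λ_C λ_D/((e^(λ_C)−1)(e^(λ_D)−1)). Because λ_D/(e^(λ_D)−1) is strictly
  decreasing, the interior optimum is unique; it exists only when the
  observed single-worm fraction is attainable (`no_solution` flag
  otherwise). The two parameters are not jointly identified: `joint_ridge`
  profiles λ_D over a λ_C grid and reports the ridge with a 3-log region
  (χ²₂/2 at 95%).

Confidence intervals are profile-likelihood intervals at a 1.92-log drop,
found by bracketed bisection from the MLE. Reported log-likelihoods include
the binomial coefficient, so the ridge maximum is an absolute binomial
log-likelihood; the constant plays no role in optimization.

## Numerical choices

* Scalar likelihood maximization: bounded Brent on λ ∈ [1e−8, 50],
  absolute tolerance 1e−8; unit tests check agreement with dense grid
  search to 1e−4. CI roots by `brentq` to 1e−8.
* The rare-colonization ridge endpoint is evaluated at λ_C = 1e−6, which is
  within 1e−6 of the analytic λ_C → 0 limit.
* Boundary occupancies (0 or n occupied) are flagged (`all_empty`,
  `none_empty`) with one-sided intervals rather than reported as infinite
  estimates.
* The quadratic ridge description is an unweighted least-squares fit of
  E[n_d] on (1, λ_C, λ_C²). The fitted coefficients depend mildly on the
  grid; the package's reference grid is λ_C ∈ (0, 3] in steps of 0.01,
  spanning the plausible range given the prevalence of empty patches (a
  mean much above 2–3 colonizations per patch is inconsistent with ~75%
  emptiness).
* Zero-truncated Poisson sampling is exact inverse-CDF on a tabulated
  cumulative distribution (table length ~ λ + 12√λ, tail mass negligible at
  double precision); the λ_D → 0 limit returns groups of exactly one.
* `mean_founders_exact` enumerates the compound distribution by repeated
  convolution of the group pmf, weighting the patch total N by the
  both-sex probability 1 − q^N − (1−q)^N. Truncation default N ≤ 400;
  residual tail mass above 1e−12 triggers a warning.

## Founder demography

Per-founder sex is independent Bernoulli(female_fraction); no within-group
sex correlation is modeled (none is identifiable from occupancy data). A
patch is *proliferative* when it holds at least one founder of each sex.
Simulations use one `numpy` Generator stream per call, fully determined by
the integer seed; Monte-Carlo runs are chunked (2×10⁶ patches per chunk) so
memory stays flat at any replicate count. Default problem sizes — 10⁶
patches for founder means (4×10⁶ in the reference script), 10⁵–5×10⁵
replicates for the fig Monte Carlo —
put Monte-Carlo standard errors one to two orders of magnitude below the
reported precision (e.g. SE ≈ 0.003 on a mean of 5.23 at 4×10⁶ patches).

## Aggregation and coexistence

Ives' intraspecific aggregation index is J = m*/(T/P) − 1 with Lloyd mean
crowding m* = Σn(n−1)/Σn and mean density taken over **all** P patches,
empty ones included. That convention makes J a consistent estimator of the
compound-process limit J∞ = E[D(D−1)]/(λ_C E[D]²) (with
E[D(D−1)] = λ_D²/(1−e^(−λ_D)) for zero-truncated Poisson groups), which is
the quantity the model predicts; defining density over occupied patches
only would not converge to it.

The interspecific index C_ab = (Σn_a n_b/Σn_a)/(Σn_b/P) − 1 is symmetric
and zero in expectation for independently distributed species.

**Competition reduction.** In the two-species aggregation-of-competitors
framework, per-capita competition felt by an individual scales with
(1 + J) conspecific and (1 + C_ab) heterospecific crowding, so aggregation
rescales the *product* of the two interspecific competition coefficients by
(1 + C_ab)²/((1 + J_a)(1 + J_b)); `competition_reduction` reports one minus
that factor. This transcription reproduces the ~89% mean reduction for the
fig-experiment parameters. Its replicate-to-replicate standard deviation is
~0.07; we could find no variant of the formula with sd ~0.19 (that value
coincides with the sd of J for the commoner species), so only the mean
should be compared across implementations.

Monte-Carlo summaries exclude replicates in which a species has zero total
founders (J undefined) and count them in `n_undefined_replicates`; at the
default fig parameters this affects a vanishing fraction (~4×10⁻⁷) of
replicates. Simulated quantities are founder counts, not post-proliferation
censuses, consistent with the inference model.

The Sokehs-style defaults use λ_C derived from occupancy fractions
*unrounded* (70% → 1.2040, 19% → 0.2107): rounding λ_C to 1.2/0.2 shifts
mean J for the rarer species by ~+0.25, well outside Monte-Carlo error.

## Spatial statistics

Geary's c = (n−1) Σ w_ij (x_i−x_j)² / (2W Σ (x_i−x̄)²), with weights from
(quadrat, row, col) grid coordinates: 0.2 m between adjacent sections
within a quadrat, a single flat between-quadrat distance (default 5 m,
configurable — real quadrat layouts vary and the analysis is insensitive to
the exact value since cross-quadrat weights are uniformly small). Schemes:
inverse distance (default), binary threshold, rook adjacency. Weight choice
is a genuine free parameter of this statistic; results on real data should
report the scheme used.

The permutation test (default 100 permutations, mirroring standard field
practice; configurable) reports both a normal-approximation p from the
z-score and the empirical rank p = (x+1)/(m+1). With the
`within_quadrat_only` restriction, values are permuted **within** quadrats,
holding quadrat-level differences fixed; restricting only the weights while
permuting globally would still let between-quadrat heterogeneity inflate
the statistic through the global variance term, defeating the purpose of
the restricted test. Species-level analyses use presence/absence (0/1)
attributes; worm densities use the 0–6 rank scale (0, 1–5, 6–10, 11–50,
51–100, 101–500, 501–1000 worms).

## Richness and association

Chao1 (abundance) and Chao2 (incidence) use the classical
f1²/(2f2) extrapolation with the (n−1)/n small-sample factor, switching to
the bias-corrected f1(f1−1)/(2(f2+1)) form when no doubletons exist.
Fisher exact tests delegate to `scipy.stats.fisher_exact`; the two-sided
rule sums tables with point probability ≤ observed, and the one-sided test
takes the tail in the direction of the observed association. The test suite
checks both against an exact-rational hypergeometric enumeration.

## Synthetic data

The generator emulates the two field designs: a ~400-patch island survey
and a 3-quadrat × 25-section fig experiment (one sample lost by default,
leaving 74). Latent worm counts follow the same compound model as the
inference; observation then applies the field protocol: lone founders are
seen as exactly 1 worm; proliferative patches are seen as
min(cap, census) with census uniform on a configurable range (default
20–1000; only its exceedance of the cap matters) and identification caps of
5 (survey) or 10 (spatial); multi-founder single-sex patches are emitted
with their raw (small) founder counts. The last rule is a deliberate
stressor: the inference model treats every single-worm patch as a lone
founder, and such patches let tests quantify the resulting (tiny) bias.
Quadrat figs carry a lognormal-overdispersed latent nematode census
(dispersion 0.6 on the log scale — Poisson variation alone rarely crosses
the wide rank bins) with optional per-quadrat multipliers that create
purely between-quadrat structure for exercising the restricted Geary test.

What the generator does **not** emulate: patch-quality heterogeneity,
vector behavior and spatially correlated dispersal, within-group sex
correlation, temporal patch turnover, species interactions on shared
patches, and misidentification. Passing recovery tests therefore shows the
estimators are correct *under the model's assumptions*, not that those
assumptions hold in any particular field system.

## Known limitations

* The single-worm likelihood is exact only for species where a lone
  individual cannot reproduce; for self-fertile species the single-worm
  count is uninformative and the ridge machinery does not apply.
* No overdispersion in colonization counts (negative-binomial extension is
  out of scope); patch-quality covariates are not modeled.
* Chao standard errors are not computed (point estimates only).
* Geary's c on rank-binned attributes inherits the information loss of the
  binning; the permutation null handles this correctly but power is reduced.
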