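# Methods

## Phenotype readouts

**Growth efficiency** is the endpoint biomass readout: `od_final −
od_initial` over a fixed incubation (24 h at the warm temperatures, the
full multi-day course in the cold). Replicates are pooled across
experiment days with no batch term; the generator offers an optional
additive day shift (`day_batch_sd`, default 0) for sensitivity checks.

**Logistic growth model.** Cold timecourses are fitted per replicate with
`OD(t) = K / (1 + exp(−R (t − x₀)))` by bounded trust-region-reflective
least squares, each parameter boxed to [−1, 10]:

* `K` — carrying capacity (OD units);
* `R` — logistic rate (per day);
* `x₀` — sigmoidal midpoint (days).

Starts are `K₀ = max OD`, `R₀ = 1/day`, `x₀ = median timepoint`; tolerances
are 1e-14, which recovers noiseless interior truths to ~1e-14 parameter
error on the 9-point day grid (0, 4, 5, 6, 7, 8, 9, 10, 11 d). Fits ending
on a box face are flagged `boundary_active`; non-convergence is carried as
`converged=False` data, not an exception, so downstream rank tests can
exclude replicates explicitly. The per-strain "average fit" is the
arithmetic mean of parameters over converged replicate fits (not a refit
of pooled points); with the day grid and noise levels in play the two
conventions differ negligibly, and parameter averaging keeps one fit per
replicate as the unit of inference.

**Viability** is quantified from a 1:10 spotting series: the selected
dilution is the densest at which *every* technical spot is countable
(below the lawn threshold, default 100 colonies/spot — a conventional
countability bound; the assay itself only distinguishes "lawn" from
countable). CFU/mL = mean technical-replicate count / spot volume /
dilution factor, normalized by end-point OD to discount dead cells that
still contribute turbidity. All-lawn series are censored above (no
estimate); all-zero series return 0 with a below-detection flag.

## Effects and epistasis

A locus's **marginal effect** is `mean(focal) − mean(reference)` on the
efficiency scale. A **stacking path** S₀ = wild type, S₁, …, S_L (each step
toggling exactly one locus, validated from the genotype bit-vectors)
decomposes the full transgenic: step effects telescope exactly to
`mean(S_L) − mean(S₀)`. The **recapitulation fraction** is computed on the
linear efficiency scale (log display of such data is treated as
presentation only).

**Additive expectation and bootstrap.** The null prediction for the joint
effect is the sum of single-swap marginal effects. Uncertainty is
propagated by resampling replicate measurements with replacement: per
iterate, each focal strain's pool is resampled once, the reference
(recipient wild-type) pool is resampled once, and the iterate's expected
joint effect is the sum of the per-locus differences. The test statistic
is the iterate-wise difference between the observed-joint and expected
bootstrap distributions, and

`p = (#{iterates with obs − exp ≥ 0} + 1) / (n_boot + 1)`

for the one-sided alternative "joint below additive" (mirrored and doubled
for the two-sided case). The add-one smoothing keeps p in (0, 1].

Two deliberate choices make this test calibrated at realistic replicate
counts (n ≈ 8); both were fixed by a design-stage simulation before any
acceptance checking:

1. **Shared reference resamples.** Every effect in the panel is measured
   against the *same* wild-type replicate pool, so the L+1 point estimates
   entering ε are strongly positively correlated (the wild-type mean
   enters ε with coefficient L−1). Resampling the reference independently
   for each term treats these as L+1 independent datasets and understates
   Var(ε) by roughly a factor of three for L = 8 — an ~19 % type-I error
   at nominal 5 %. Sharing one reference draw per iterate across all terms
   reproduces the estimator's true covariance structure. The standalone
   `bootstrap_effect` (single effect, no cross-term coupling) keeps fully
   independent focal/reference streams.
2. **m = n−1 resampling.** Size-n with-replacement resampling understates
   the SE of a mean by √((n−1)/n) (≈ 6 % at n = 8, compounding to ~7.7 %
   type-I error). Drawing m = n−1 of n makes the bootstrap SE of a mean
   exactly unbiased. `resample_size="n"` restores plain resampling.

With both, the measured type-I error is ≈ 0.06 over thousands of additive
panels at α = 0.05 — the small residual excess is the usual
normal-vs-Student effect of estimating the replicate variance from ~7
degrees of freedom per strain, which a percentile-type bootstrap cannot
remove; a studentized bootstrap would, at the cost of abandoning the
simple resampling objects the analysis is defined in terms of.

**Interaction classification** per locus compares the swap's effect alone
(vs wild type) with its effect on top of the stacking path (X vs X−1),
from bootstrap CIs at the configured level: *sign* if both CIs exclude
zero with opposite signs; *masking* if detectable alone but not in
combination; negative/positive *magnitude* if both are detectable with the
same sign and the iterate-wise difference of magnitudes excludes zero;
*none* otherwise. The **path trend test** is the exact binomial upper tail
at success probability ½ on the number of beneficial steps; the default
criterion counts point-positive steps (counting only significantly
positive steps is available; with 7/8 positive steps the tail is 9/256 ≈
0.035).

**Rank tests.** Strain pairs are compared with Wilcoxon rank-sum tests:
exact null distribution when the combined n ≤ 25 and there are no ties,
otherwise the normal approximation with mid-rank tie correction. One-sided
families point the alternative at the hypothesized direction (stress
temperatures); the growth control at 28 °C is two-sided. Families —
all comparisons computed in one invocation — are corrected with
Benjamini–Hochberg.

## The synthetic panel

The generator emulates the study design: per strain, `n_days` batches of
2–8 replicate cultures (default 8 × 1), efficiency = true phenotype +
N(0, `noise_sd`), cultures standardized to OD 0.1 at the start; logistic
timecourses on the 9-point day grid with Gaussian OD noise clamped at
zero; Poisson colony counts at 10⁻¹…10⁻⁵ with 3 µL spots, two technical
replicates, counts ≥ the lawn threshold censored as `LAWN`. Interaction
regimes: additive; magnitude damping (each added locus contributes
`effect · f^(rank−1)`; a solver picks f to place the joint truth at a
stated fraction of the additive sum); masking (the target locus
contributes nothing in the presence of any masker); sign reversal.

**Defaults are a stated world, chosen once.** No replicate-level variances
or ΔOD effect sizes are published for this design, so the scale was fixed
a priori: baseline efficiency 0.4 ΔOD, per-locus effects 0.15 ΔOD,
`noise_sd` 0.05 ΔOD, 8 replicates/strain. This keeps every single swap
below a 1.4-fold benefit (1.375×) while giving it a per-locus z ≈ 3
against the wild type — matching a panel in which every single-swap effect
is individually rank-test significant — and the donor wild type saturates
at 2.0 ΔOD, a typical rich-medium 24 h endpoint. Wild-type purebreds are
encoded with reserved tokens, not bit-strings: the donor wild type is not
the all-ones genotype (it differs genome-wide), which is why the default
panel recapitulates ~46 % of the divergence rather than tying the joint
effect to the endpoint gap.

What a green synthetic test does **not** establish: the generator is
phenomenological (no thermal-death or cell-cycle kinetics), homoscedastic
across strains, and day-batch-free by default; real plate data with
strain-dependent variance or batch structure would need the stratified
options and could weaken the stated operating characteristics.

## Numerical choices and degenerate inputs

* Replicate vectors are put in canonical (sorted) order before reduction,
  so all estimates are exactly invariant to input row order.
* In the epistasis test, iterate differences within 1e-12 of zero (scaled
  by the data magnitude) count as ties with the null side, so an exactly
  additive noise-free panel returns the maximal p instead of an arbitrary
  float-summation sign.
* Tables are CSV, UTF-8, "." decimals; floats serialized by shortest
  round-trip repr and re-read with `float_precision="round_trip"`, making
  write/read cycles bit-exact. `LAWN` is a literal token in count fields.
* Config files are YAML; omitted keys take documented defaults
  (n_boot 10,000, α 0.05, CI level 0.95, seed 2021). The stacking order is
  user-supplied (only the first locus of the emulated series is fixed by
  convention); locus order is config-owned, one source of truth for
  genotype bit alignment.
* Pipelines consume one seed; stages draw from deterministically spawned
  substreams, so reruns are byte-identical and stage skipping never
  perturbs other stages.

## Known limitations

* The percentile-type bootstrap retains a ~1 percentage-point type-I
  excess at n = 8 (see above).
* `average_fit` averages parameters, not curves; for strongly asymmetric
  replicate fits a pooled refit could differ.
* No mixed-model or batch-correction inference is provided, matching the
  pooled-replicates design; the generator's day-shift option exists only
  to probe sensitivity.
* Higher-order (pairwise/three-way) interaction decompositions are out of
  scope; the analysis tests joint-vs-additive and per-locus background
  dependence only.
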