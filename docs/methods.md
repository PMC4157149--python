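# Methods

## Model and assumptions

`tagbias` works at the level of a single biallelic causal variant D, a
single biallelic marker M on the same haplotype background, a binary
exposure X and a binary outcome Y. Assumptions baked into the machinery:

- **Random mating / HWE at the haplotype level.** A diploid subject is two
  independent draws from the haplotype joint; genotype distributions are
  Hardy–Weinberg at each locus and the diploid view is always derived,
  never stored (`haplotypes.diploid_expansion`).
- **Multiplicative per-allele effects.** Disease risk scales as R^d and
  exposure probability as θ^d in the causal allele count d. Under this
  assumption the per-allele marker risk ratio computed from diploid
  genotypes factorizes and equals the haploid (chromosome-level) marker RR
  exactly — the bridge between the allele-level algebra and dosage-coded
  regression. This is verified to 1e-12 in the test suite.
- **No direct marker effect.** M affects Y only through its LD with D, so
  the marker-level GLM is the mixture of the causal GLM over Pr(D | M, X).
- **Ratio arithmetic on unnormalized masses.** Marker RRs are ratios of
  risk-weighted to unweighted marker-class masses; all baselines and
  stratum normalizations cancel, so results are independent of disease and
  exposure prevalence. Observed odds ratios are accepted on the risk-ratio
  scale (rare-outcome convention); users of common outcomes should treat
  the outputs as approximations.

The three causal routes to G–E dependence (mediation, pleiotropy,
confounding by e.g. population structure) induce the same statistical
object — a D–X association summarised by the tilt θ — so no DAG-specific
computation is provided.

## Exposure-stratification conventions

Two conventions relate the haplotype joint to exposure strata, chosen via
`convention=`:

- `baseline_unexposed` (default in `glm.build_joint_dmx`): the supplied
  joint describes unexposed chromosomes; exposed-stratum masses are the
  cell-wise tilt `joint · θ^d`, renormalized. This reproduces the worked
  examples exactly and is the convention the forward risk engine uses.
- `marginal`: the joint is the population marginal and
  Pr(X=1 | d) = κ·θ^d with κ solved to hit a target exposure prevalence
  (feasibility κ·θ ≤ 1 enforced).

The simulator defaults to `marginal` (exposure assigned per subject from
the causal dosage, κ solved at the diploid level), which is the natural
generative direction for a cohort. It also offers `baseline_unexposed`
(draw X first, then two haplotypes iid from the stratum distribution):
within-stratum haplotype independence makes the allele-level stratum marker
RRs *exactly* the analytic ones, which is why the calibration tests against
the worked example use it. Under `marginal` the unexposed stratum couples a
subject's two haplotypes at order κ²(θ−1)², negligible at test tolerances
but not identically zero.

## Numerical choices

- Haplotype masses validated (nonnegative, sum to 1 within 1e-9), never
  clipped; Fréchet-bound violations raise errors naming the bound, with the
  boundary itself accepted.
- Positive D′ means the causal allele is enriched on the minor-marker
  background; the r² route requires an explicit sign because r² is
  sign-blind.
- Coefficients (log scale) are the internal currency; ratios are converted
  at the CLI boundary.
- The sensitivity inversion solves sequentially in closed form when
  h_Dm = 0 (D′ = 1, causal MAF ≤ marker MAF: the M = 0 class carries no
  causal alleles, so the baseline equation is linear in R and the tilted
  equation linear in θ). Otherwise a damped 2-D Newton iteration in
  (log R, log θ) runs from the initial guess (rr₀, rr₁/rr₀), halving steps
  until the residual norm decreases, tolerance 1e-12, cap 200 iterations,
  with a sequential Brent fallback exploiting the triangular structure
  (the baseline-stratum RR never involves θ). Solutions are reported at
  full precision together with the forward residual.
- The IRLS fitter aggregates subject rows to unique (marker, exposure)
  cells, so fitting cost is independent of sample size; convergence is a
  1e-10 coefficient-change criterion with separation and rank deficiency
  reported, never silently returned.
- Power uses Wald expected-information asymptotics for the prospective
  logistic fit (intercept, carrier, exposure, product) to case-control
  data. `sample_size_for_interaction` evaluates the information at the
  alternative — the scenario's carrier×exposure cell model with the
  interaction cell overridden on the odds scale to the requested detectable
  ratio — so effect size and information refer to the same data-generating
  model, and Monte-Carlo power at the returned n lands on the target.
  Defaults: balanced cases/controls, exposure prevalence 0.5, baseline
  disease risk 0.01, carrier coding; the "order-of-magnitude" conclusions
  for tiny LD-induced interactions are insensitive to all of them.

## Identifiability of the inversion

Two observed stratum effects determine two unknowns (R, θ), but the
tilted-stratum equation is non-monotone in θ when LD is incomplete:
solutions come in pairs θ ↔ h_dM·h_dm / (R·h_DM·h_Dm·θ), both reproducing
the observations exactly. At D′ = 1 — the recommended maximum-correlation
assumption, and the setting of all worked examples — the partner root
degenerates and the inversion is unique. For D′ < 1 the solver returns the
root its iteration finds and reports the partner in `rr_exposure_alt`;
users should regard the exposure-side solution as set-valued there.

The stratum labelling matters: the *baseline* stratum is the one whose
haplotype distribution is untilted. For the worked inversion example the
assignment (baseline = marker effect 0.906, tilted = 0.979) is the only one
with a positive solution; the reverse is reported as infeasible rather than
silently relabelled. Inverted solutions reproduce three-decimal published
roundings of the disease-side ratios and are within ±0.005 of the
exposure-side ones; the residual discrepancy is consistent with the inputs
themselves being published at three decimals.

## What the simulator emulates — and what it does not

`simulate` draws haplotype pairs, dosage-dependent exposure, and Bernoulli
outcomes from the causal GLM (identity/log/logit), seeded and
bit-reproducible; case-control sampling is rejection from the cohort model
with an explicit iteration budget. It emulates exactly the idealised world
of the analytic machinery: one causal locus, one marker, binary exposure,
no covariates, no genotyping error at the marker itself, no population
structure beyond what the D–X tilt encodes, and exposure assignment that
factorizes over alleles. Passing tests therefore demonstrate internal
consistency of the algebra and its estimators, not robustness to real-data
complications (multi-locus LD, continuous or misclassified exposures,
covariate adjustment, selection).

Problem sizes used by the test suite were chosen to keep Monte-Carlo error
well below the assertion bands: cohorts of 2×10⁵–10⁶ subjects for 3-SE
recovery checks, 200 replicates of 3×10⁴ for SE calibration, 500
cell-multinomial replicates for power calibration, and ≥1000 randomized
draws for the no-interaction condition sweep.

## Known limitations

- Biallelic loci, two loci, binary exposure only; no VCF/genotype-file
  ingestion — parameters are supplied directly.
- Additive-scale (risk-difference) interaction measures, RERI, case-only
  estimators: out of scope.
- Confidence intervals are not propagated through the inversion (would
  require the covariance of the observed stratum effects).
- The GWAS-scale interaction ratio is reported by the risk-ratio engine;
  treating published odds ratios as risk ratios is exact only in the
  rare-outcome limit.
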