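# Methods

## Scope and data model

The package analyses one continuous, positive trait (the motivating case is
hominin endocranial volume, ECV, in cm³) through three table types: a
binned lineage time series (per-bin age, mean, SD, n), individual specimen
records (group, sex, value), and per-species per-sex summaries for
comparative work.  Ages are time before present, in years or generations;
conversion is real division by the generation time (no flooring).  The
canonical bin order is oldest first, because divergence is reckoned
ancestor → descendant.  A missing SD is legal only in n = 1 bins, and such
bins are silently excluded only from computations that need a phenotypic SD
(haldane denominators); everywhere else they participate normally.

## Rates and the mode of evolution

Two rate scales are maintained in parallel and always agree in sign:

* haldanes: (z₂ − z₁)/(s_p·g), with s_p the pooled SD of the two endpoint
  samples ((n−1)-weighted, requiring n ≥ 2 on both sides).  Pooling the
  endpoints rather than using a global SD matches the per-interval
  definition of the rate.
* mean-standardized: ln(z₂/z₁)/g, dimensionless per generation.  This is
  the scale on which the neutral nulls and selection gradients live.

The log-rate/log-interval (LRI) regression uses **all pairwise** bin
combinations, not only adjacent bins, because the slope is only identified
from a spread of interval lengths.  Rates of exactly zero (and any below
`classify_tolerance`, default 0) are dropped before taking logs and their
count reported.  The fit is ordinary least squares of log₁₀|rate| on
log₁₀(interval); the mode call compares the 95% slope interval with the
theoretical anchors 0 (directional), −0.5 (random walk) and −1 (stasis)
and is made only when exactly one anchor is contained, otherwise
`ambiguous`.  The containment test is widened by a relative 1e-9 so that
exact synthetic fits (zero residual variance, hence zero-width intervals)
still contain their anchor.

A caveat documented here deliberately: for a *single* lineage the LRI slope
of a true random walk has an irreducible sampling spread (SD ≈ 0.2 with 20
bins) because long-interval rates are dominated by one realized
displacement.  The mean slope across replicates converges tightly to −0.5,
and that is what the calibration checks assert; per-replicate mode calls
are reliable (>90%) only for the regimes that admit a noise-free limit
(directional, stasis).

## Neutral nulls and selection gradients

On the mean-standardized scale the among-lineage variance of neutral
outcomes after t generations is e·t/N_e under constant-heritability drift,
and c·σ²_m·t under mutation–drift equilibrium.  The accumulation constant c
is not uniquely fixed by the model family's common statements, so it is an
explicit parameter (default 2: between-lineage divergence accruing at twice
the per-generation mutational variance) and is written into every output
record rather than being buried in code.

The divergence test reports a signed z = d/σ_B and a standard-normal tail
probability.  One-tailed means the upper tail P(Z ≥ z) — the probability
under the null of divergence at least as large *in the observed direction*,
the natural reading of "was evolution too fast?" — so the test has size α
under the null, which the calibration suite verifies empirically (2,000
simulated drift lineages; rejection rate inside the binomial 95% band
around 5%).  Two-tailed is 2·P(Z ≥ |z|), capped at 1.  The default is
two-tailed; both are derivable from the reported z.

Selection gradients use β_μ = Δz̄_μ/e.  Converting a haldane rate to the
mean-standardized scale requires the phenotypic CV (rate_μ ≈ rate_h · CV);
where a worked value assumes CV = 0.10 that conversion is made explicitly
at the call site, never inside the function.

Default parameter values used in examples and calibration, all overridable:
e = 0.009 (dimensionless evolvability of ECV), N_e = 5000, generation time
29 y, σ²_m = 4 × 10⁻⁶ per generation (mean-square standardized mutational
variance of murine mass/body-composition traits), c = 2.

## Variation

CVs are proportions internally, percent only in rendered output.  The
small-sample correction (1 + 1/(4n)) is applied by default below n = 30
(fossil samples are tiny and bias-prone); the `corrected` flag is always
recorded.  The pooled within-sex CV divides the (n−1)-weighted within-sex
SD by the n-weighted grand mean; unknown-sex specimens are excluded with a
reported count, never imputed.  ΔCV intervals default to the independent
two-sample percentile bootstrap with 10,000 resamples; the asymptotic
alternative uses var(CV) ≈ CV²(0.5 + CV²)/n summed across groups.
Degenerate bootstrap resamples (non-positive mean — impossible for positive
trait data, guarded anyway) are redrawn with a cap and warning.

Known limitation: the percentile bootstrap undercovers slightly at n = 30
(measured ≈ 93% for a nominal 95% on lognormal data, at the edge of the
calibration band asserted in the tests); at larger n it converges to the
asymptotic interval, which the agreement test checks at n = 100.

Percentile placement of a focal CV among species CVs uses the midpoint tie
convention, 100·(#below + ½·#equal)/n — 0 below the minimum, 50 at the
median of an odd set, 100 strictly above the maximum.

## Synthetic data

Trait dynamics are simulated directly on the log-mean scale as a
population-level diffusion, not by individual-based reproduction: the nulls
are phrased as among-population variance formulas on that scale, and
calibration needs thousands of replicates cheaply.  Per generation:
neutral drift adds Normal(0, e/N_e); directional adds e·β plus the drift
increment (N_e = ∞ disables drift exactly); mutation–drift adds
Normal(0, c·σ²_m); stasis draws independent Normal(0, σ_stasis)
perturbations about the start.  σ_stasis defaults to 0.02 (2% wobble on the
log scale) — no principled value exists for an abstract optimum, and the
LRI slope of the stasis regime is invariant to it, so it only sets the
scale of simulated wobble.

Fossil-style sampling bins a path at evenly spaced generations and draws
lognormal individuals (positivity plus a clean CV parameterization) with
within-population CV 0.10 by default (matching the phenotypic CV implied by
the haldane↔mean-standardized conversion above), optional sexual
dimorphism (male/female ratio, sex factors normalized so the expected
overall mean equals the path mean) and multiplicative measurement error.
The comparative-table generator draws per-species true CVs from a
lognormal (median 6%, log-SD 0.35 — primate ECV CVs cluster around a few
percent), species means from a wide lognormal spanning small-bodied
primates to great apes, dimorphism uniform on [1.0, 1.6], and emits two
per-sex summary rows per species (48 species by default) plus a truth
table for recovery tests.

Reproducibility: every generator is a pure function of its config including
the seed; the trajectory and sampling stages consume independent
sub-streams spawned from the one seed, so changing the sampling noise never
perturbs the trajectory.

What the generator does *not* emulate — and hence what passing tests do not
establish about real fossil data: dating uncertainty, non-uniform and
taphonomically biased sampling through time, mixed or uncertain taxonomic
attribution, spatial population structure and gene flow, and any plastic
(environmentally induced) component of variation.

## Problem sizes in the calibration suite

The stochastic checks use: 2,000 drift-null lineages of 10⁴ generations
(test size); 200 directional lineages (β* = 0.002, N_e = 10⁶, t = 10⁴;
gradient recovery within 5%); 200 replicates per regime of 20-bin,
5,000-generation lineages (mean LRI slope within ±0.1 of each anchor); and
1,000 lognormal ΔCV simulations at n = 30 per group with 10,000 bootstrap
resamples (interval coverage).  These sizes give Monte-Carlo error
comfortably inside each asserted band while keeping the whole suite fast on
a single CPU.
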