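# Methods

## Demand model

Demand is treated as a categorical distribution over the `r` distinct
antigen-negative combinations that appear in historical requests. Each
category's probability is its request count divided by the total request
count; rows with zero requests are dropped rather than kept at p = 0,
because a positive target on a zero-probability category makes every
coverage probability degenerate (it can never be met). Category order is
preserved from the input; sorting by probability is a presentation concern.

Amalgamation of substitutable combinations (filling an E-K- request with
C-E-K- stock) is deliberately not modelled: it would raise probabilities
without changing per-category donor needs, and loses resolution. ABO/RhD
compatibility logic is likewise out of scope. Each donor is assumed to
belong to exactly one category, and probabilities are taken per combination,
never factored per antigen (antigen occurrences are not independent).

Targets for a planning window scale counts proportionally and round **up**
(ceiling), so rarely requested categories keep a non-zero target even in
short windows — conservative toward meeting demand, since the source data's
rounding convention is not published. The `at-least-one` regime (every
requested combination gets target 1) is the one used for panel sizing.

## Allocation model and bounds

Typing `S` donors is one Multinomial(S, Pvec) draw; marginals are
Binomial(S, p_j) with mean `p_j S` and variance `p_j(1−p_j)S`. The pmf is
evaluated in log space via log-gamma so cohort sizes around 2×10^5 do not
overflow. Binomial tails use the exact regularized incomplete beta (scipy),
never a normal approximation: at the 95% threshold the bounds hinge on tail
probabilities of order 10^-4, far below normal-approximation accuracy.

Mallows' inequality brackets the all-targets coverage probability P_S
between a Bonferroni-type lower bound and a product (and exponential) upper
bound built from those marginal tails. Numerical choices:

- the lower bound is clipped at 0 (the raw expression goes negative for
  small S); ordering against the exact value is preserved;
- `S < K = Σ k_j` is flagged infeasible (pigeonhole: P_S = 0);
- the minimal cohort size S_C searches the lattice `S = K + i·step`
  (default step 100, matching 3-significant-figure reporting; step 1 gives
  the exact minimum). The lower bound is monotone non-decreasing in S, so
  bisection between a failing point and a doubled passing point equals a
  linear scan, which the tests check;
- an exhaustive-enumeration oracle (`exact_coverage`) sums the pmf over all
  qualifying allocations, enumerated as compositions of the surplus S − K
  shifted by the targets; it refuses above a configurable term cap
  (2×10^6) and exists to validate the bounds on small instances, not to
  size panels.

## Monte Carlo validation

For a candidate S, `n_samples` (default 10,000) independent Multinomial
draws are scored by the success percentage `100 × (1 − failures/r)`, where a
failure is a category below its target. The headline statistic is the
**minimum** over samples — a size is accepted when even the worst sample
meets the required percentage — with the mean and the zero-failure fraction
(which estimates P_S itself, and must sit inside the Mallows bounds up to
MC error) as diagnostics. Sample i draws from a generator spawned
deterministically from (seed, i) (numpy SeedSequence), so runs are
reproducible and parallelizable independent of batch size. Sweeps evaluate
S = round(μ·K) over a list of multipliers μ.

## Panel timeline

With `q` donors screened per annum, annual non-return fraction `m`, and
uniform arrival of new screenings through the year (hence first-year
attrition m/2, i.e. effective intake M = q(1 − m/2)), the screened panel
follows D_{y+1} = (1−m)D_y + M, with closed form

    D_y = (1−m)^y D_0 + (M/m)(1 − (1−m)^y)

and steady state M/m. Years are integral (planning tables are annual);
fractional-year inversion is not provided. `q = weekly_returning × fraction
× 365/7` is rounded to the nearest whole donor by default — published
tables print integer q — with the unrounded rate selectable; the two paths
differ by a couple of donors at a 12-year horizon, which is why table
comparisons allow ±3. Years-to-target returns "never" when the steady state
does not exceed the target; the required screening fraction for a deadline
scans a 1-percentage-point grid by default; the maintenance rate comes from
the fixed point q(1 − m/2) = m·target.

Default scenario parameters (units: donors, donors/week, decimals/annum):
panel 542,891; 13,500 weekly returning donors; m = 0.13; genotype scenario
1% weekly screening with D_0 = 9,772 already screened; phenotype scenario
5% with D_0 = 65,689. These are the published planning assumptions and are
exposed as `default_panel_params`.

## Synthetic demand generator

The generator emulates the published *shape* of real request data — the
only aspects public: r = 403 (genotype) or 299 (phenotype) categories, top
probability exactly 0.41 (pinned to c-E-K-), remaining mass decaying
rapidly with roughly 93% of categories below frequency 0.004. The decay
family is a modelling choice: a power law by default (geometric available),
with the exponent fitted by a deterministic grid search so the
sub-threshold fraction is as close to the stated 93% as the discrete
category grid allows. With the top probability pinned, a 403-category power
law cannot go below ≈93.5% sub-threshold, so the fitted shape sits there —
comfortably within the ≥90% fidelity assertion used in tests. Probabilities
are a deterministic function of the shape parameters; the seed randomises
only the synthetic labels, which are syntactically valid antigen-negative
strings over the genotyping/serology alphabets and claim no real
frequency–phenotype correspondence.

What the generator does **not** emulate: the real data's extreme rare tail
(its minimum probability is unpublished; the synthetic minimum is ~4×10^-4,
which is why synthetic at-least-one sizing lands near 19k donors rather
than the published 205k), temporal demand structure, and any linkage
between antigen combinations. Tests passing on synthetic profiles therefore
demonstrate correctness of the machinery and directional behaviour
(success rises with S/K; S = K almost never meets all targets), not the
published cohort sizes, which require the original per-category
probabilities. When such a table is supplied as `label,probability` CSV it
is used verbatim in place of a synthetic profile.

## Problem sizes in the tests

Bound-vs-enumeration checks run on 500+ random instances with r ≤ 4,
S ≤ 12, where exhaustive enumeration is exact and fast. Monte Carlo
agreement uses 10,000 samples on small instances; the end-to-end sizing
check validates the C = 95 cohort on the 403-category synthetic profile
with 500-sample runs across five seeds; directional sweeps use 800 samples
on 120-day proportional targets from a 27,000-request synthetic table.
These sizes keep the whole suite under a minute while leaving every
statistical assertion at ≥4 standard errors of slack.

## Known limitations

- Demand is assumed stationary and uniform over time; seasonality and
  donation-frequency caps are not modelled.
- The attrition model is deterministic in expectation; no stochastic
  donor-return variability.
- Bounds assume independent-marginal tails in the Bonferroni/product sense;
  they are valid bounds for the Multinomial but can be loose when S is
  close to K (the lower bound clips at 0 there).
- The 85% sizing row is supported (any 0 < C < 100) but nothing downstream
  consumes it.
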