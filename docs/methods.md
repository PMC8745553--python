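# Methods

## Expression discretization

Each gene's expression across a cohort is called over-expressed (+1) when
strictly above `mean + n·std`, under-expressed (−1) when strictly below
`mean − n·std`, and normal (0) otherwise (population std, ddof 0). The
multiplier *n* is calibrated on 27 housekeeping genes (ACTB … YWHAZ): for
each housekeeping gene, *n* solves

```
#{x > mean + n·std} + #{x < mean − n·std} = round(f · N)
```

with target fraction `f = 0.30` by default. The flagged count is a step
function of *n* changing only at the breakpoints `|x − mean|/std`, so the
equation is solved exactly by scanning the intervals between consecutive
breakpoints — never iteratively. Two numerical choices:

- **Ties.** On discrete data the exact count can be unattainable; the
  closest achievable count wins, preferring the smaller count (fewer flags)
  on ties, then the smaller *n*.
- **Interval interior.** The returned *n* is the midpoint of the achieving
  interval rather than its left edge. The left edge sits exactly on a
  breakpoint, where re-evaluating `x > mean + n·std` downstream can flip a
  sample on floating-point rounding; the midpoint reproduces the chosen
  count bit-for-bit.

The per-gene solutions are averaged over the housekeeping panel and the
averaged *n* is applied uniformly to every gene in that cohort. The
constraint is solved per gene before averaging (not pooled across the
panel). Copy-number matrices are categorized with inclusive thresholds
(default ±0.3 on log-ratio input; ±0.5 passes already 3-level data through
unchanged); thresholds are explicit configuration, never inferred.

## Implication rules

For a pair of 3-level variables, each of the four rule types (A↑⇒B not↓,
A↑⇒B not↑, A↓⇒B not↓, A↓⇒B not↑) is falsified by exactly one corner cell
of the 3×3 contingency table. Following prediction logic, a rule's *scope*
is the error mass expected under independence, `U = e_exp = p̂(premise) ·
p̂(error state)`, and its *precision* is the proportional error reduction
`∇ = 1 − e_obs/e_exp` (defined as 0 when `e_exp = 0`). Samples with a
normal (0) call in the premise variable can never falsify a rule; they
only dilute the marginals.

A rule is significant when a one-tailed z-test on the error-cell depletion
exceeds `z_crit = 1.64` (α = 0.05) *and* both scope and precision are
positive. Two variance conventions are implemented:

- `conditional` (default): the hypergeometric variance of the error-cell
  count with all margins fixed,
  `Var = n_r·n_c·(N−n_r)·(N−n_c) / (N²·(N−1))`, with a 0.5 continuity
  correction. With the margins fixed, the exact null of the test is the
  permutation distribution of the labels, and this statistic is its normal
  approximation: measured against a 10⁴-replicate permutation oracle on
  random Dirichlet-multinomial tables (N ≤ 60) the two decisions disagree
  on <1% of tables, and the statistic is never anticonservative.
- `prediction_logic`: the classic one-proportion form
  `z = (e_exp − e_obs)·√N / √(e_exp·(1 − e_exp))`, which treats `e_exp` as
  known. Since `e_exp` is estimated from the margins this overstates the
  variance roughly twofold at typical margins; the realized type-I error is
  ≈0.01 at nominal 0.05. It is retained for comparability with the
  prediction-logic literature, not as the default.

**Attainability of the nominal level.** Corner-cell counts are small
integers, so the exact conditional null is discrete: even the permutation
test itself rejects ~3% of independent pairs at nominal α = 0.05 (at
N = 100–200 and 30/40/30 margins). Any statistic calibrated to the exact
null therefore realizes a type-I rate in roughly the 0.02–0.05 band; the
test suite asserts that band rather than a point value.

`best_rule` scores all four types (the four corner cells already cover
both orientations of the pair — each B→A rule shares its error cell, and
all statistics, with one A→B rule) and returns the significant rule of
maximal precision, breaking ties by larger scope and then by a fixed type
order, so results are order-independent and deterministic.

**Cross-cohort intersection** keeps an edge when it is significant in every
cohort with a replicating *direction class*: the two reciprocal rules of a
positive relation (A↑⇒B not↓ and A↓⇒B not↑) count as the same direction,
as do the two of a negative relation. With a strong true edge both
reciprocal rules typically reach precision 1 and the per-cohort winner is
decided by a noisy scope tie-break; requiring the literal identical rule
type would discard genuinely replicating edges on that noise. Edges whose
direction class flips across cohorts are dropped. Exact-type matching is
available (`match="exact"`).

No multiplicity correction is applied across the rule family; the study
design uses per-test α, and FDR control is exposed only as configuration
downstream of the rule lists.

## Network assembly

Non-seed genes are retained when linked to at least `min_seed_degree = 2`
*distinct* seed genes (a gene connected twice to one seed through different
omics layers counts once). Seeds are always retained; an empty result is
valid. The radiotherapy contrast compares stage III/IV irradiated patients
surviving < 20 months vs > 58 months by Welch's t-test (pooled variance is
a flag); the group bounds are configuration.

## Dependency screens

Screens are consumed as processed genes × cell-lines score matrices (CERES
for CRISPR, DEMETER2 for RNAi); the model fits themselves are not
reimplemented, only their published output standardization contracts:

- CRISPR: per cell line, `x' = (x − med_ne) / (med_ne − med_e)` anchors the
  non-essential control median at 0 and the essential control median at −1
  exactly. At least 3 measured controls per set per line are required;
  coincident medians raise an error.
- RNAi: genes are first averaged across their tested lines, the same
  two-point map is anchored on the control medians *of the averages*, and
  the per-line matrix is rescaled by that same affine map so the −0.5
  threshold applies to it.

Both maps are affine and hence rank-preserving per line. Significance is
strict (`score < −0.5`; missing cells are never significant). The majority
proliferation rule is inclusive (≥ 50% of the gene's *tested* lines — the
per-gene non-missing count, not the panel size — in either assay); the
count rule is strict (> `min_lines`, default 10). Control genes are not
excluded from the calls: an essential control legitimately satisfies
either rule, and callers filter as needed.

## Survival model

The risk score is the raw linear predictor `Σ β_g·x_g` of a multivariate
Cox model (lifelines), without mean-centering or baseline term — an
explicit convention, since transferring a fixed cutoff from training to
testing is only well-defined once the centering convention is stated. The
stratification boundary is assigned to the high-risk stratum (score <
cutoff ⇒ low; the default cutoff −0.74 is a configuration constant, not
re-derived). The strata are compared with a two-sided log-rank test, and
the hazard ratio with 95% CI comes from a one-covariate Cox fit on the
high-risk indicator; display truncation of the survival curves (default
120 months) never alters the test. Cohort splits are seeded,
disjoint and exhaustive, with the training size `round(fraction·N)`.

## Drug response

Out-of-window activities are categorical by definition: IC50/EC50 above
the maximum tested dose ⇒ resistant, below the minimum ⇒ sensitive (the
default window 0.0006–10 µM is the eight-dose PRISM design). In-window
values (boundaries inclusive) are trichotomized by log10-scale tertiles of
the window — an in-house convention, isolated behind the categorization
function and recorded in output metadata, since the source analyses defer
the in-window rule to earlier work. The trichotomy is monotone: a larger
activity never moves a line toward sensitive.

Response-linked genes are selected on the strict sensitive-vs-resistant
contrast (partial responders excluded) by Welch's t-test at p < 0.05 and a
linear-scale fold change `mean(sensitive)/mean(resistant)` outside
[0.5, 2]. Log-scale matrices must be de-logged via `log_base`; fold change
is a ratio and is meaningless on log values. A *gene* is drug-sensitive
when selected as higher-in-sensitive for at least one (drug, dataset)
table and never selected as higher-in-resistant in any. The two-proportion
z-test for the mRNA–protein correlation contrast is pooled; two-tailed by
default, one-tailed available.

## Query signatures

Isoform signatures partition the proliferation genes co-expressed with a
seed isoform by the rule consequent under the given seed direction: with
the seed up-regulated, A↑⇒B not↓ sends the partner up and A↑⇒B not↑ sends
it down; with the seed down-regulated, the down-premise rules apply.
Edges written with the seed as target are mirrored first. The
mechanism-of-action signature is `UP = (epithelial ∪ drug-sensitive) \
proliferation` and `DOWN = mesenchymal ∪ (proliferation \ epithelial) ∪
{CD27, CD274}`; any residual up/down overlap is an error naming the
offenders, and every exported signature is checked disjoint and nonempty.
Connectivity-map thresholds traditionally applied downstream of these
lists (query p < 0.05, |connectivity score| > 0.9) are interpretation
constants for the external service and are not computed here.

## Synthetic data

The generators emulate the input schemas with planted, parameterized
structure; a fixed seed gives byte-identical output, and every generator
returns a ground-truth record alongside the data.

- *Expression*: background genes iid standard normal; housekeeping genes
  unit variance. Each planted pair shares a latent factor with loading
  equal to the edge strength (`x = s·f ± √(1−s²)·ε`), which depletes the
  corner cells of the discretized table, and strength maps monotonically
  to rule precision — the reason a latent factor is used rather than a
  copula. A gene participating in several edges accumulates loadings,
  rescaled to keep its variance near 1 (so a seed gene serving many
  targets is realistically weaker per edge). Distinct cohort ids reuse the
  same truth with independent noise.
- *CNV*: states drawn iid from {−1, 0, 1} (default 20/60/20%); a dosage
  edge shifts the target gene's expression by `strength·sd` per copy
  state.
- *Survival*: exponential event times with hazard `λ0·exp(Σβx)` (λ0 sets a
  30-month baseline median), uniform censoring with the upper bound
  calibrated by bisection to the target rate (realized within ±3%),
  stage and radiotherapy columns for the clinical filters. Default
  coefficients (0.5, −0.5, 0.3, 0, 0, 0, 0.2) give a mix of strong, null
  and weak effects.
- *Screens*: essential controls centered at −1, non-essential at 0
  (sd 0.15); planted dependent genes score ≈ −0.8 in 80% of their lines;
  missingness (default 5%) applied to non-control genes only. Panel sizes
  default to 78 (CRISPR) and 92 (RNAi) lines.
- *Drug activities*: sensitive/resistant lines receive log-uniform values
  strictly outside the dose window, partial responders inside; planted
  response genes shift by 1.5 sd between groups.

What passing on these generators does *not* show: robustness to RNA-seq
count noise (Gaussian suffices for a rank-ish 3-level discretization
target, but overdispersion is not modelled), batch effects, probe-to-gene
mapping artifacts, non-proportional hazards, or informative censoring.
Cohort-scale results on the public accessions additionally depend on an
unstated train/test split seed and cannot be reproduced from the synthetic
conditions.

## Problem sizes

The validation suites run at desk scale by design: 27 × 100 samples for
the discretization contract; 250 random tables × 10⁴ permutations for the
z-test/oracle comparison; 10 planted edges at strength 0.9 in two cohorts
of 200 samples for recovery; 2000 null pairs for the type-I estimate; 1000
patients for coefficient recovery and 500 replicates of 150 + 150 patients
for CI coverage. These sizes put Monte-Carlo error comfortably inside each
asserted tolerance.
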