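# Methods

## Problem and notation

For a biallelic variant, write the allele-count table as `a, b` (effect /
other allele counts in cases) and `c, d` (controls), with group allele
numbers `m1 = a + b = 2·N_case` and `m0 = c + d = 2·N_control` on autosomes.
The per-allele odds ratio is `OR = ad/(bc)`; the pooled effect-allele
frequency is `AF_total = (a + c)/(m1 + m0)`; the Wald standard error of
`log OR` for a pure table is `SE = sqrt(1/a + 1/b + 1/c + 1/d)`. `ccfreq`
inverts these relations to recover group-specific frequencies when only
summary statistics are published.

## Total-AF route

Substituting the frequency parametrisation into the OR and the
sample-size-weighted mean identity leaves a single quadratic in
`AF_control`:

```
A x² + B x + C = 0
A = (N_control/N_case)(OR − 1)
B = OR(1 − (N_total/N_case)·AF_total) + (N_control + N_total·AF_total)/N_case
C = −(N_total/N_case)·AF_total
```

Exactly one root lies in [0, 1] whenever `OR ≠ 1` (verified by a randomized
sweep in the test suite); `AF_case` follows from the weighted-mean identity.
Numerical choices:

- `OR = 1` makes the equation linear; it is solved directly as
  `AF_control = AF_total` instead of dividing by a vanishing `A`.
- The quadratic is solved in the cancellation-stable form
  (`q = −(B + sign(B)·sqrt(B² − 4AC))/2`, roots `q/A` and `C/q`), because
  `B²` dominates `4AC` by orders of magnitude at rare variants.
- Roots within `1e-8` outside [0, 1] are accepted and clamped; anything
  else is a per-variant failure (NaN in batch mode), never a global abort.
- The input must be the allele-anchored total AF. Feeding a folded MAF
  silently breaks the anchoring and adds variability; the API therefore
  only documents AF input.

Missing primaries are derived on read: `OR = exp(beta)`, and
`SE = |beta|/z` with `z = Φ⁻¹(1 − p/2)`. p-values below the smallest normal
double (~2.2e-308) raise an explicit underflow error advising use of the
test statistic.

## SE route

Eliminating `a, b, c` from the four-equation system
`{a+b = m1, c+d = m0, OR = ad/(bc), SE² = 1/a + 1/b + 1/c + 1/d}` and
clearing denominators yields a cubic in `d` with a spurious root at zero;
the remaining quadratic is

```
A = (OR − 1)² + OR·SE²·m1
B = −OR·m0·(2(OR − 1) + SE²·m1)
C = OR·m0·(OR·m0 + m1)
```

(derived symbolically from the system; its correctness is enforced by the
round-trip tests). Each root materialises a candidate table via
`a = OR·m1·(m0 − d)/(OR·m0 − (OR − 1)·d)`, `b = m1 − a`, `c = m0 − d`.

**Identifiability.** For balanced designs the two candidate tables are a
table `T` and its exact case-control-and-allele mirror `(d, c, b, a)`,
which share OR, SE and allele numbers. The inverse problem is therefore
two-valued: `(OR, SE)` cannot distinguish `(maf_case = x, maf_control = y)`
from `(y, x)`. Following the assumption that the frequency being estimated
is the minor allele's, the solver selects the root whose table is
*minor-concordant* (effect-allele frequency ≤ 0.5 in both groups), falling
back to control-frequency ≤ 0.5, then to any all-cells-positive table.
Consequences, all covered by tests:

- tables whose effect allele is minor in both groups round-trip exactly
  (to 1e-6 after folding);
- an input whose OR was anchored to the major allele returns the
  case/control mirror of the source table's folded values — the two
  candidates differ by at most `|maf_case − maf_control|`, which is small
  at GWAS-typical effect sizes, so the practical impact is limited to
  frequencies near 0.5;
- outputs are folded to [0, 0.5] and `maf_total` is the allele-number-
  weighted minor-allele count fraction, consistent with the folding.

Degenerate/inconsistent inputs: a negative discriminant (an OR/SE pair no
positive table can produce) or roots with out-of-range cells raise a
per-variant no-solution error; `|disc| < 1e-12·B²` is treated as a double
root for robustness at `OR ≈ 1`. Real-valued (non-integer) cells are
accepted without rounding, since regression SEs do not come from exact
tables. For X and Y chromosomes the allele numbers are `2·n_XX + n_XY` and
`n_XY` per group respectively.

## Bias correction

Covariate-adjusted logistic regressions report conditional SEs that differ
from the marginal table SEs, which biases the SE route (MAFs are
underestimated, increasingly so at higher MAF). With a harmonized panel of
proxy MAFs standing in for the truth, the correction fits, within five
proxy-MAF bins `[0.0,0.1) [0.1,0.2) [0.2,0.3) [0.3,0.4) [0.4,0.5]`, an OLS
quadratic `estimated = β0 + β1·proxy + β2·proxy²`; the bias at MAF `x` is
`B(x) = fitted(x) − x`.

Design choices where the procedure was genuinely open:

- **Application at the estimate.** At correction time only the estimate
  exists (the panel does not cover all variants), so `B` is evaluated at
  the variant's estimated total MAF, with bin assignment by the estimate
  as well. This is first-order consistent when the bias is small;
  inverting the per-bin polynomial instead was rejected because a
  quadratic need not be invertible on its bin. A residual fraction of the
  bias therefore remains (on noiseless 10%-shrunk data the corrected
  values are 0.99 of truth, not 1.0).
- **One shared `B` per variant** is subtracted from the case, control and
  total MAFs alike; the model is fitted on total MAFs only.
- **Minimum 30 pairs per bin** (configurable); an under-populated bin
  borrows the nearest populated bin's polynomial with a logged warning.
  Fits are independent per bin; discontinuities at bin edges are accepted
  behaviour.
- Harmonization is by normalized chromosome ("chr1" ≡ "1") + position;
  allele-pair mismatches are dropped, proxy frequencies anchored to the
  opposing allele are flipped (`f → 1 − f`) before folding, duplicates and
  empty overlaps are hard errors.

## Simulator

`simulate_study` emulates a liability-threshold case/control GWAS:

- population MAFs ~ Uniform(0.05, 0.5) (configurable); genotypes
  Binomial(2, p) under HWE — defaults 10,000 variants, 100 causal;
- causal effects ~ Normal(0, 1), with the genetic score centred and
  rescaled so it contributes exactly `genetic_variance_fraction` (default
  0.2) of liability variance; covariates (binary p = 0.5; plus a 5-level
  categorical, dummy-coded, and a Normal(30, 20) continuous variable in
  the 3-covariate layout) contribute `covariate_variance_fraction`
  (default 0.2) the same way; the remainder is Gaussian noise;
- case status by liability order statistic, so case/control counts are
  exact (the published scenarios specify exact counts such as 600/5400);
- all randomness flows from one seed (bit-identical reruns).

Summary statistics come from one additive-dosage logistic regression per
variant, fitted for all variants simultaneously by a batched Newton solver
(the Hessians decompose into shared-column cross products, so each
iteration is a few BLAS products over all variants; agreement with
sequential `statsmodels.Logit` fits is ~1e-6, and the saturated 2×2 fit
equals `ln(ad/bc)` analytically). Monomorphic, separated and non-converged
variants become NaN rows with a logged warning.

What the simulator deliberately does *not* model: linkage disequilibrium,
population structure/kinship, imputation dosage uncertainty, sex-chromosome
genotypes, or ascertainment beyond the liability threshold. Passing tests
therefore show the estimators' algebraic and sampling behaviour under a
clean HWE design, not robustness to those real-data features.

## Evaluation

Lin's concordance correlation coefficient,
`ccc = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)` with population (1/n) moments,
scores agreement with the identity line; reports also give per-bin CCC and
mean bias using the reporting bins `[0.0,0.1] (0.1,0.2] … (0.4,0.5]`
(left-open except the first — note these differ deliberately from the
left-closed fitting bins above; each convention is used where it is
conventional). Incomplete pairs are dropped pairwise with a logged count.
Each reconstruction route is scored on the scale it outputs: allele-
anchored AF for the total-AF route, folded MAF for the SE route.

At the default study conditions the no-covariate scenarios give case-side
CCCs ≈ 0.9999 (total-AF route) and 0.981–0.995 (SE route, rising with
sample size), and the 3-covariate 5000/5000 scenario drops the SE route
below 0.95 with a negative mean bias in the (0.3, 0.5] bin while the
total-AF route stays ≈ 1 — the pattern the bias correction exists for.
These numbers are recomputed, not quoted, by `scripts/acceptance.py` and
`tests/test_acceptance.py`. The acceptance script uses 10,000-variant
scenarios up to 5000/5000, sizes chosen to match the published simulation
design while completing in minutes on a single CPU.

## Known limitations

- The SE route's case/control-mirror ambiguity near MAF 0.5 is inherent to
  the summary statistics, not fixable by implementation.
- The bias polynomial extrapolates poorly outside the proxy-MAF range it
  was fitted on; under-populated bins borrow neighbours rather than
  extrapolate.
- The correction assumes the proxy panel is ancestrally comparable to the
  study; no adjustment for ancestry mismatch is attempted.
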