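# ccfreq

Reconstruct **case-specific and control-specific allele frequencies** from
GWAS summary statistics.

Many secondary analyses — external common controls, group-specific polygenic
scores, case-case comparisons — need the allele frequencies of cases and
controls separately, but published GWAS summary statistics usually report
only the pooled (total) frequency, or no frequency at all. `ccfreq`
implements two closed-form reconstructions from per-variant summary
statistics plus the case/control sample sizes, a proxy-panel bias correction
for the second route, a synthetic-GWAS simulator, and concordance-based
evaluation tools. It is aimed at statistical geneticists reusing public
summary statistics.

## The two reconstructions

**From the total AF.** With `OR` the per-effect-allele odds ratio and
`AF_total` the pooled effect-allele frequency,

```
AF_total = (N_case·AF_case + N_control·AF_control) / N_total
OR       = AF_case(1 − AF_control) / ((1 − AF_case)·AF_control)
```

eliminating `AF_case` yields a quadratic in `AF_control` with exactly one
root in [0, 1]. The outputs stay anchored to the effect allele. When `OR`
and `AF_total` derive from an actual allele-count table the inversion is
exact; with estimated ORs the only error is the OR's sampling noise, so this
route is accurate across the MAF spectrum, covariates or not.

**From the standard error.** The log-OR standard error of an allelic 2×2
table satisfies `SE² = 1/a + 1/b + 1/c + 1/d` with `a+b` and `c+d` fixed by
the group allele numbers (2N on autosomes), giving a four-equation system
that reduces to a quadratic in `d`. Only folded **minor** allele frequencies
in [0, 0.5] are identifiable (allele anchoring is lost), and when the source
GWAS adjusted for covariates the reported SEs are not plain table SEs: the
reconstruction then systematically **underestimates** common-variant MAFs.

**Bias correction.** Using a reference panel of proxy MAFs (e.g. a gnomAD
population) harmonized to the GWAS variants, `ccfreq` fits a second-order
polynomial of estimated on proxy MAF within five MAF bins
([0.0,0.1) … [0.4,0.5]) and subtracts the fitted bias from every variant's
case/control/total MAF estimates — including variants absent from the panel.

## Worked example

```python
from ccfreq import AFInputs, SEInputs, solve_casecontrol_af, solve_casecontrol_se

# a study of 500 cases / 500 controls reported OR = 1.714 and total AF = 0.25
solve_casecontrol_af(AFInputs(or_value=12/7, af_total=0.25, n_case=500, n_control=500))
# CaseControlAF(af_case=0.3, af_control=0.2)

# the same variant via OR + SE only (allele numbers 2N = 1000 per group)
solve_casecontrol_se(SEInputs(or_value=12/7, se_value=0.1049376,
                              alleles_case=1000, alleles_control=1000))
# CaseControlMAF(maf_case=0.30000018..., maf_control=0.20000013..., maf_total=0.25000015...)
```

The first call says: the effect allele has frequency 0.30 in cases and 0.20
in controls — exactly the allele-count table (300, 700, 200, 800) that
produced the inputs. The second recovers the same values as folded MAFs from
OR and SE alone (to ~2e-7, the precision of the quoted SE).

The simulation + evaluation loop (here scaled down to 2,000 variants):

```python
from ccfreq import SimulationConfig
from ccfreq.evaluate import evaluate_scenario

evaluate_scenario(SimulationConfig(n_case=500, n_control=500,
                                   n_variants=2000, n_causal=20, seed=42))
# {'ccc_af_case': 1.0, 'ccc_af_control': 1.0,
#  'ccc_se_case': 0.9795, 'ccc_se_control': 0.9798, ...}
```

Lin's concordance correlation coefficient (CCC) between true and estimated
case/control frequencies is ~1 for the total-AF route and slightly lower for
the SE route, whose estimates carry the extra SE sampling noise.

Everything is also exposed as a CLI — `ccfreq af`, `ccfreq se`,
`ccfreq correct`, `ccfreq simulate`, `ccfreq evaluate`, `ccfreq grid`; see
`ccfreq --help`.

## Limitations

- The SE route cannot distinguish a table from its case-control-and-allele
  mirror for balanced designs; it returns the minor-allele-concordant
  solution (see `docs/methods.md`).
- No genome-build liftover and no ancestry adjustment of the proxy panel;
  harmonization is by position and allele pair only.
- X/Y variants need explicit karyotype counts (`ccfreq se --chromosome X`).
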