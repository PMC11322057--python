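# Methods

## Data model

A cohort is a panel of biallelic SNPs (`Locus`: rsID, gene, major/minor
allele symbols — the major/minor designation follows the reference
population, not the sample) plus nuclear families. Each `Family` has a
mother, one offspring, an optional father (absent = dyad) and a binary
status (`case`/`control`, assigned from the offspring row's linkage-format
phenotype: 1 = control, 2 = case, 0/−9 = missing, which excludes the family
with a logged warning). Genotypes are unordered allele pairs normalised to
sorted tuples; `None` marks failed genotyping. PED input accepts letter or
1/2 allele coding (1 = major, 2 = minor); any `0` allele makes the whole
genotype missing.

Missing data are handled per locus: a family member untyped at one SNP is
excluded from that SNP's analyses only (complete-case by locus), so the
effective N differs across loci and roles — as it does in the source
tables, where fewer fathers than mothers were genotyped.

Mendelian checking reports a violation iff no assignment of one maternal
and one paternal allele yields the offspring genotype (for dyads: mother
and offspring share no allele). Violating families are excluded from
transmission counting at that locus — the only analysis a violation
invalidates — but retained in case–control counting. The source study
reports no rule for (and no instances of) such inconsistencies; this
package takes the least destructive defensible choice and logs the
exclusion count.

## Case–control tests

Counting: each typed individual of the requested role contributes two
alleles to the 2×2 allelic table or one genotype to the 2×3 table
(major-hom / het / minor-hom).

- **Pearson χ²** is uncorrected (no Yates continuity correction); the
  published 2×2 statistics reproduce only without correction.
- **Fisher's exact test** is two-sided by the point-probability method
  (sum of hypergeometric probabilities ≤ that of the observed table), via
  scipy; an independent full-enumeration oracle backs it in the tests.
- **Test selection** `auto` uses Fisher when any expected cell of a 2×2 is
  below 5, else Pearson; the rule can be overridden (`pearson`/`fisher`)
  since the source publication does not state its switching rule.
- **Odds ratios are crude** (cross-product) with the Woolf CI
  exp(ln OR ± 1.96·√Σ1/nᵢⱼ) and a Wald p-value, delegated to statsmodels'
  `Table2x2`. Although the source text mentions multivariate logistic
  regression, every printed OR that is derivable from its counts equals the
  crude OR; a single-predictor logistic fit is provided as a cross-check
  (`logistic_odds_ratio`) and provably coincides with the crude OR on a
  saturated 2×2. Covariate adjustment is out of scope.
- **Orientation is explicit.** Every OR carries an `orientation` string
  naming the numerator category and group, because the source tables flip
  direction between rows (e.g. the paternal rows are oriented to the major
  allele). Default: minor allele (or collapsed risk class) in cases versus
  controls.
- **Zero cells** get the Haldane–Anscombe +0.5 correction on all four
  cells, with a `haldane` flag on the result. No published table needs it,
  but simulated sparse tables can.
- **Genotype collapsing**: dominant = carriers (het + minor-hom) vs
  major-hom; recessive = minor-hom vs the rest; `wrt="major"` swaps the
  reference allele (one published maternal row collapses with respect to
  the allele that is rarer in that sample rather than the declared minor
  allele).
- **Hardy–Weinberg**: Pearson goodness of fit of (Np̂², 2Np̂q̂, Nq̂²) with
  q̂ estimated from the counts, df = 1; monomorphic samples return χ² = 0
  flagged. Convention: tested in controls.
- Multiple-testing correction is off by default (the source applies none);
  standard corrections can be applied downstream to the returned p-values.

## TDT

For each complete, Mendelian-consistent triad the transmitted allele of
each parent is the one forced by subtracting the other parent's possible
contributions from the offspring genotype. Only heterozygous parents are
informative. When both parents and the offspring are heterozygous the pair
of transmissions is necessarily one copy of each allele but parent
assignment is unresolvable; such records are flagged ambiguous. The
statistic is (a − b)²/(a + b) against χ²(1), where a/b count transmissions
and non-transmissions of the allele of interest.

Ambiguous records always contribute one transmission of each allele to the
overall stratum. For the mother/father strata the policy is explicit
because the source does not state one: `exclude` (default) drops them from
parental strata and reports the count — note the source's parental counts
sum exactly to its overall counts, implying either no ambiguous triads or a
silent assignment — while `split` credits half a transmission of each
allele to each parent. The TDT is always run within one arm (case or
control triads), never pooled; the control-arm TDT is meaningful in this
design because the mothers, not the offspring, are the patients.

## Maternal × fetal combinations

Mothers are collapsed at the maternal locus and offspring at the fetal
locus (dominant collapsing by default, matching the published grouping of
minor-allele-containing vs minor-allele-free), giving a 2×4 case–control
table over the class combinations. The global test is Pearson χ² with
df = K − 1 — the source labels this "one-way ANOVA" but its printed values
are exactly the 2×4 Pearson statistics, so the Pearson test is implemented.
Per-category ORs are computed against a reference category, by default the
one with the largest combined count ("highest incidence"); this automatic
rule recovers all three published reference rows. On a saturated table
these crude ORs equal the coefficients of a logistic regression on category
indicators (verified in the tests), which reconciles the published
"multiple logistic regression" wording with crude computation.

## Simulator

`SimParams` defaults are the study conditions: 74 case and 80 control
families; 18/74 and 2/80 missing-father fractions; the seven study SNPs
with minor-allele frequencies set to their control-sample parental values
rounded to two decimals (0.19, 0.50, 0.47, 0.42, 0.42, 0.40, 0.40 — chosen
once from the published control counts as the realistic operating point);
Mendelian transmission (τ = 0.5); no genetic effects; baseline prevalence
0.05 (the clinical incidence is 5–10%).

Parents are drawn genotype-wise from Hardy–Weinberg proportions at q; a
heterozygous parent transmits the minor allele with probability τ
(transmission distortion is the TDT's alternative hypothesis). Disease
probability is logistic: logit(prevalence) plus log-odds terms for maternal
and fetal risk-class membership and an optional maternal×fetal interaction
term. Families are accepted by status until each arm is full (rejection
sampling, mimicking case–control ascertainment of families), then fathers
are deleted at the configured per-arm fractions. One seeded generator
(`numpy` PCG64) drives everything; the same seed reproduces a byte-identical
PED file, and `estimate_power` spawns independent substreams per replicate.
A draw cap (default 4×10⁶ families) guards against unreachable designs.

Loci are simulated independently (no linkage disequilibrium): the analyses
in scope are single-locus, or cross-locus between genes on different
chromosomes (*KIR2DL4* on 19, *HLA-G* on 6). The generator emulates the
sampling structure the analyses assume — HWE parents, Mendelian or
distorted transmission, logistic ascertainment — but not genotyping error,
population stratification, LD, or missing genotypes within typed members;
passing calibration tests therefore validates the statistics under those
assumptions, not robustness to artefacts of real data.

Monte-Carlo checks computed by the test suite: the TDT's empirical type-I
error over 5,000 null cohorts of 150 triads; recovery of a fetal dominant
OR of 2.5 (q = 0.36, 500 families/arm, median over 200 replicates); allele
frequency and HWE calibration on large single-locus cohorts. These sizes
are the packaged defaults for the checks and keep each run at desk scale.

## Reproduction audit

The packaged fixtures transcribe the published integer count tables
(allele counts, genotype counts, transmitted/untransmitted counts,
combination counts); printed statistics are stored separately and used only
as the comparison reference, so every reported statistic is recomputed.
Each recomputed OR, χ² and TDT statistic is graded on the printed scale:
`match` (≤ 0.002), `rounding` (≤ 0.01), `inconsistent` (larger — the
printed value cannot be derived from its own printed counts). ORs are
accepted under either contrast direction (and either collapsing allele) to
accommodate the source's per-row orientation changes before being declared
inconsistent. Published p-values are recomputed but not graded, since the
source does not state which test produced each one.

Of the 84 graded statistics, 75 match to printed precision and **nine are
irreconcilable with their own printed counts** under every admissible
orientation:

| statistic | printed | recomputed |
|---|---|---|
| fetal rs9380142 allelic OR | 2.802 | 2.133 |
| fetal rs9380142 allelic χ² | 19.352 | 10.756 |
| maternal rs1051456 allelic χ² | 2.854 | 3.633 |
| paternal rs9380142 allelic OR | 1.389 | 1.343 |
| fetal rs9380142 dominant OR | 2.196 | 2.679 |
| fetal rs9380142 recessive OR | 1.633 | 2.298 |
| maternal rs9380142 recessive OR | 0.430 | 0.750 |
| paternal rs1063320 dominant OR | 1.182 | 0.611 |
| paternal rs1063320 recessive OR | 1.464 | 1.286 |

Supporting observations: the maternal rs9380142 recessive row's printed CI
(0.367–1.533) brackets the recomputed 0.750, not the printed 0.430, and its
printed p matches the recomputed OR's Wald p — the printed OR appears to be
a transcription error; the paternal rs1063320 dominant OR and CI duplicate
the adjacent rs1630185 row verbatim; and the maternal rs1051456 printed p
(0.056) matches the recomputed χ² (3.633), not the printed one. The audit
also notes that the paternal control genotypes at rs1063320 reject
Hardy–Weinberg at the 5% level (p = 0.046), despite the blanket published
claim of control-group HWE (informational; not graded). The CLI
(`triadtest reproduce`) exits non-zero only if an inconsistency appears
*outside* this known set, so the audit doubles as a regression gate for the
package itself.

## Numerical and design notes

- Confidence intervals use z = 1.96 on the log-OR scale throughout,
  matching the published intervals.
- TDT counts are exact small integers (halves under the `split` policy);
  the statistic is formed in rational arithmetic before the χ² tail call.
- Ties in the automatic combination-reference rule (equal combined counts)
  resolve to the first category in table order.
- Degenerate inputs fail loudly with typed exceptions: zero-margin tables,
  empty roles, TDT with no informative transmissions, undefined HWE on
  empty groups, unreachable simulation designs.
- Known limitations: autosomal biallelic SNPs only; no VCF input, no
  multi-allelic sites, no X-linked inheritance, no haplotype/LD analysis,
  no covariate-adjusted regression, no formal interaction
  (departure-from-multiplicativity) test for the combination analysis.
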