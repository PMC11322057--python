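# triadtest

Family-triad genetic association analysis for case–control studies of
maternal–fetal traits, built around the design used in candidate-gene
studies of preeclampsia: two arms of mother–(father)–offspring units
genotyped at a small panel of biallelic SNPs (here, maternal *KIR2DL4* and
fetal *HLA-G*), where some families lack a genotyped father (dyads).

It is aimed at genetic epidemiologists who want the classic desk-scale
toolkit for this design as tested, scriptable code:

- **Case–control association** per locus and family role (mother, father,
  offspring): allelic (2×2) and genotypic (2×3) tables, uncorrected Pearson
  χ², Fisher's exact test (automatic for sparse tables), crude odds ratios
  with Woolf 95% confidence intervals, dominant/recessive genotype
  collapsing, and Hardy–Weinberg goodness-of-fit testing.
- **Transmission disequilibrium test (TDT).** For each complete triad the
  transmitted/untransmitted allele of each heterozygous parent is inferred;
  the statistic is χ² = (a − b)²/(a + b) with df = 1, where *a* counts
  transmissions of the allele of interest and *b* non-transmissions —
  overall and stratified by transmitting parent, with an explicit policy
  for parent-of-origin–ambiguous double-heterozygous triads.
- **Maternal × fetal combined genotypes:** 2×K contingency tables of
  collapsed maternal class × collapsed fetal class, a global Pearson
  heterogeneity test (df = K − 1), and per-category odds ratios against the
  highest-incidence reference category.
- **A synthetic cohort simulator** (parents drawn from Hardy–Weinberg
  proportions, Mendelian or distorted transmission, logistic disease model
  with maternal/fetal/interaction effects, case–control ascertainment by
  rejection sampling) plus Monte-Carlo power estimation.
- **A reproduction auditor** that recomputes every derivable statistic of
  the source study from its published count tables and grades agreement
  with the printed values.

Analyses follow a model/results pattern: a model object is built from a
`Cohort` and `fit()` returns a results object carrying estimates,
uncertainties and a `summary()`.

## Worked example

Published genotype counts can be analysed directly. The fetal *HLA-G*
rs1063320 genotype counts (cases CC/CG/GG = 19/36/19, controls 37/29/14)
give the allelic and dominant-model associations:

```python
from triadtest import Locus, AllelicAssociation, GenotypicAssociation

# ... cohort built from a PED file (read_ped) or from genotype counts ...
print(AllelicAssociation(cohort, "rs1063320", "offspring").fit(test="pearson").summary())
```

```
Allele association at rs1063320 (HLA-G), offspring
          G    C
case     74   74
control  57  103
OR = 1.807 (95% CI 1.145-2.853)  [G in case vs control]
chi2 = 6.500 (df=1), p = 0.01079  [pearson]
```

The minor G allele is carried by 50% of case fetuses versus 35.6% of
control fetuses; its odds are 1.8-fold higher in cases, and the uncorrected
χ² rejects equal allele frequencies at p ≈ 0.011. Under a dominant model
(`GenotypicAssociation(..., model="dominant").fit()`) G-carriers have
OR = 2.491 (95% CI 1.259–4.927).

The same pipeline runs on simulated cohorts. With the default study design
(74 case / 80 control families, 18 and 2 missing fathers) and a fetal
dominant odds ratio of 2.5 at rs9380142:

```python
from triadtest import TransmissionDisequilibriumTest
from triadtest.simulate import SimParams, Effect, simulate_cohort

cohort = simulate_cohort(SimParams(seed=7, fetal_effects=(Effect("rs9380142", odds=2.5),)))
print(TransmissionDisequilibriumTest(cohort, "rs9380142", "case").fit().summary())
```

```
TDT at rs9380142, case triads, allele of interest A (ambiguity policy: exclude)
informative parental transmissions: 55
  all   : a=36 b=19  chi2=5.255 p=0.02189, ambiguous records: 14
  mother: a=11 b=6  chi2=1.471 p=0.2253, ambiguous records: 7
  father: a=18 b=6  chi2=6.000 p=0.01431, ambiguous records: 7
```

Heterozygous parents of affected pregnancies transmitted the risk allele A
36 times and withheld it 19 times — an excess over the Mendelian 50:50
expectation (χ² = 5.26, p = 0.022). The 14 ambiguous records are the seven
double-heterozygous triads with heterozygous offspring, which count toward
the overall stratum (one transmission of each allele) but are excluded from
the parental strata and reported.

A command-line interface mirrors the library:

```bash
triadtest simulate --seed 7 --out cohort.ped
triadtest assoc --ped cohort.ped --loci cohort.loci.tsv --role offspring --level allele
triadtest tdt   --ped cohort.ped --loci cohort.loci.tsv --status control
triadtest combo --ped cohort.ped --loci cohort.loci.tsv --maternal rs649216 --fetal rs9380142
triadtest reproduce          # audit the published tables (see below)
```

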