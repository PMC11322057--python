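"""Transmission inference and the transmission disequilibrium test."""

import numpy as np
import pytest

from triadtest import (
    MendelianInconsistencyError,
    TransmissionDisequilibriumTest,
    UndefinedStatisticError,
    infer_transmissions,
    tdt_by_stratum,
    tdt_statistic,
)
from triadtest.simulate import SimParams, simulate_cohort
from triadtest.tdt import count_transmissions

from conftest import make_family, single_locus_cohort


class TestInferTransmissions:
    def test_het_mother_hom_father(self, ga_locus):
        fam = make_family("f1", ga_locus, "GA", "GG", "GG")
        mom, dad = infer_transmissions(fam, ga_locus)
        assert (mom.parent, mom.transmitted, mom.untransmitted,
                mom.informative) == ("mother", "G", "A", True)
        assert dad.informative is False and not dad.ambiguous

    def test_double_het_hom_child(self, ga_locus):
        fam = make_family("f1", ga_locus, "GA", "GA", "AA")
        recs = infer_transmissions(fam, ga_locus)
        assert all(r.transmitted == "A" and r.informative for r in recs)

    def test_double_het_het_child_is_ambiguous(self, ga_locus):
        fam = make_family("f1", ga_locus, "GA", "GA", "GA")
        recs = infer_transmissions(fam, ga_locus)
        assert all(r.ambiguous and r.informative and r.transmitted is None
                   for r in recs)

    def test_dyad_and_incomplete_yield_nothing(self, ga_locus):
        assert infer_transmissions(
            make_family("f1", ga_locus, "GA", None, "GG"), ga_locus) == []
        assert infer_transmissions(
            make_family("f2", ga_locus, "GA", "GG", None), ga_locus) == []

    def test_violation_raises(self, ga_locus):
        fam = make_family("f1", ga_locus, "GG", "GG", "GA")
        with pytest.raises(MendelianInconsistencyError):
            infer_transmissions(fam, ga_locus)


class TestStatistic:
    @pytest.mark.parametrize("a, b, chi2, p", [
        (28, 8, 11.111, 0.001),
        (14, 4, 5.556, 0.018),
        (19, 10, 2.793, 0.095),
    ])
    def test_published_count_values(self, a, b, chi2, p):
        res = tdt_statistic(a, b)
        assert res.chi2 == pytest.approx(chi2, abs=1e-3)
        assert res.p_value == pytest.approx(p, abs=1e-3)
        assert res.df == 1

    def test_balanced_transmissions(self):
        res = tdt_statistic(9, 9)
        assert res.chi2 == 0.0 and res.p_value == 1.0

    def test_undefined_without_transmissions(self):
        with pytest.raises(UndefinedStatisticError):
            tdt_statistic(0, 0)


class TestCohortTDT:
    def small_cohort(self, ga_locus):
        return single_locus_cohort(ga_locus, [
            ("GA", "GG", "GG", "control"),   # mother transmits G
            ("GA", "GG", "GA", "control"),   # mother transmits A
            ("GA", "GA", "AA", "control"),   # both transmit A
            ("GA", "GA", "GA", "control"),   # ambiguous pair
            ("GG", "GA", "GG", "control"),   # father transmits G
            ("GG", "GG", "GG", "control"),   # uninformative
            ("GA", None, "GG", "control"),   # dyad: skipped
            ("GA", "GG", "GG", "case"),      # other arm: ignored
        ])

    def test_counts_by_stratum_exclude_policy(self, ga_locus):
        fit = TransmissionDisequilibriumTest(
            self.small_cohort(ga_locus), ga_locus, "control").fit()
        # overall: A-transmissions a = 1 (fam2) + 2 (fam3) + 1 (ambiguous pair)
        assert (fit.overall.a, fit.overall.b) == (4.0, 3.0)
        assert (fit.mother.a, fit.mother.b) == (2.0, 1.0)
        assert (fit.father.a, fit.father.b) == (1.0, 1.0)
        assert fit.overall.n_ambiguous == 2  # two records, one triad
        assert fit.mother.n_ambiguous == 1

    def test_split_policy_credits_halves(self, ga_locus):
        fit = TransmissionDisequilibriumTest(
            self.small_cohort(ga_locus), ga_locus, "control",
            ambiguity="split").fit()
        assert (fit.mother.a, fit.mother.b) == (2.5, 1.5)
        assert (fit.father.a, fit.father.b) == (1.5, 1.5)

    def test_stratum_sum_invariant(self, ga_locus):
        fit = TransmissionDisequilibriumTest(
            self.small_cohort(ga_locus), ga_locus, "control").fit()
        total = fit.mother.a + fit.mother.b + fit.father.a + fit.father.b
        assert total + fit.overall.n_ambiguous == fit.overall.a + fit.overall.b

    def test_mendel_violations_excluded_and_counted(self, ga_locus):
        cohort = single_locus_cohort(ga_locus, [
            ("GA", "GG", "GG", "control"),
            ("GG", "GG", "GA", "control"),   # impossible child
        ])
        fit = TransmissionDisequilibriumTest(cohort, ga_locus, "control").fit()
        assert fit.n_skipped_mendel == 1
        assert fit.overall.a + fit.overall.b == 1

    def test_no_informative_transmissions_is_an_error(self, ga_locus):
        cohort = single_locus_cohort(ga_locus, [("GG", "GG", "GG", "control")])
        with pytest.raises(UndefinedStatisticError):
            TransmissionDisequilibriumTest(cohort, ga_locus, "control").fit()

    def test_functional_wrapper_matches_model(self, ga_locus):
        cohort = self.small_cohort(ga_locus)
        res = tdt_by_stratum(cohort, ga_locus, "control")
        fit = TransmissionDisequilibriumTest(cohort, ga_locus, "control").fit()
        assert [(r.stratum, r.a, r.b) for r in res] == [
            (s, fit.strata[s].a, fit.strata[s].b)
            for s in ("all", "mother", "father")]


def brute_force_counts(cohort, locus, status, stratum):
    """Independent recount: enumerate parental allele assignments directly."""
    a = b = 0.0
    for fam in cohort.families_with_status(status):
        if fam.father is None:
            continue
        m, f, c = (fam.mother.get(locus.rsid), fam.father.get(locus.rsid),
                   fam.offspring.get(locus.rsid))
        if None in (m, f, c):
            continue
        assignments = sorted({
            (ma, fa) for ma in m for fa in f
            if tuple(sorted((ma, fa))) == tuple(sorted(c))})
        for parent, gt, pos in (("mother", m, 0), ("father", f, 1)):
            if gt[0] == gt[1]:
                continue  # uninformative
            if stratum not in ("all", parent):
                continue
            alleles = {asg[pos] for asg in assignments}
            if len(alleles) == 1:
                if alleles == {locus.minor}:
                    a += 1
                else:
                    b += 1
            elif stratum == "all":
                a += 0.5
                b += 0.5
    return a, b


@pytest.mark.parametrize("stratum", ["all", "mother", "father"])
@pytest.mark.parametrize("seed", [1, 7, 23])
def test_counts_match_brute_force_on_simulated_cohorts(ga_locus, stratum, seed):
    params = SimParams(
        n_case_families=0, n_control_families=20,
        dyad_fraction_case=0.0, dyad_fraction_control=0.1,
        loci=((ga_locus, 0.4),), seed=seed)
    cohort = simulate_cohort(params)
    fit = TransmissionDisequilibriumTest(cohort, ga_locus, "control").fit()
    a, b = brute_force_counts(cohort, ga_locus, "control", stratum)
    assert (fit.strata[stratum].a, fit.strata[stratum].b) == (a, b)


def test_null_transmission_fraction_is_binomial(ga_locus):
    """With tau = 0.5 the minor-transmission fraction stays within 3 sigma."""
    params = SimParams(
        n_case_families=0, n_control_families=3000,
        dyad_fraction_case=0.0, dyad_fraction_control=0.0,
        loci=((ga_locus, 0.5),), seed=42)
    cohort = simulate_cohort(params)
    fit = TransmissionDisequilibriumTest(cohort, ga_locus, "control").fit()
    n = fit.overall.a + fit.overall.b
    assert n > 2000
    assert abs(fit.overall.a / n - 0.5) < 3 / (2 * np.sqrt(n))


def test_distorted_transmission_shifts_counts(ga_locus):
    params = SimParams(
        n_case_families=0, n_control_families=1500,
        dyad_fraction_case=0.0, dyad_fraction_control=0.0,
        loci=((ga_locus, 0.5),), transmission_distortion=0.7, seed=5)
    cohort = simulate_cohort(params)
    fit = TransmissionDisequilibriumTest(cohort, ga_locus, "control").fit()
    frac = fit.overall.a / (fit.overall.a + fit.overall.b)
    assert 0.65 < frac < 0.75
    assert fit.overall.p_value < 1e-6
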