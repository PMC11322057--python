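"""Synthetic triad/dyad cohort generator and Monte-Carlo power estimation.

The generator emulates the design of a case-control family study of
preeclampsia: two arms of mother-(father)-offspring units, parents drawn
genotype-wise from Hardy-Weinberg proportions at each locus's minor-allele
frequency, offspring receiving one allele per parent (a heterozygous parent
transmits the minor allele with probability ``tau``; 0.5 is the Mendelian
null), and family case status assigned by rejection sampling against a
logistic disease model combining maternal, fetal and maternal-x-fetal
genotype effects.  Fathers are then removed from a configurable fraction of
families in each arm to mimic incomplete triads.

Defaults reproduce the study conditions: 74 case / 80 control families,
18/74 and 2/80 missing-father fractions, the seven study SNPs at their
control-sample parental minor-allele frequencies, no genetic effects, and a
5% baseline prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import expit, logit

from .cohort import Cohort, Family, Locus, genotype
from .errors import SimulationError, ValidationError

#: The seven study SNPs with control-sample parental minor-allele frequencies.
STUDY_PANEL: tuple[tuple[Locus, float], ...] = (
    (Locus("rs649216", "KIR2DL4", "C", "T"), 0.19),
    (Locus("rs1051456", "KIR2DL4", "C", "G"), 0.50),
    (Locus("rs34785252", "KIR2DL4", "C", "A"), 0.47),
    (Locus("rs9380142", "HLA-G", "G", "A"), 0.42),
    (Locus("rs1063320", "HLA-G", "C", "G"), 0.42),
    (Locus("rs1630185", "HLA-G", "A", "G"), 0.40),
    (Locus("rs1130363", "HLA-G", "G", "A"), 0.40),
)


@dataclass(frozen=True)
class Effect:
    """A per-locus genotype effect on disease odds.

    ``odds`` multiplies the disease odds of individuals in the risk class
    defined by ``model`` ('dominant': minor-allele carriers; 'recessive':
    minor-allele homozygotes).
    """

    rsid: str
    odds: float
    model: str = "dominant"


@dataclass(frozen=True)
class ComboEffect:
    """A maternal-class x fetal-class interaction effect on disease odds.

    The multiplier applies when the mother is in (``maternal_risk=True``) or
    out of (False) the risk class of ``maternal_model`` at
    ``maternal_rsid``, and analogously for the offspring.
    """

    maternal_rsid: str
    fetal_rsid: str
    odds: float
    maternal_model: str = "dominant"
    fetal_model: str = "dominant"
    maternal_risk: bool = True
    fetal_risk: bool = True


@dataclass(frozen=True)
class SimParams:
    """Design parameters of a simulated triad cohort (defaults = study design)."""

    n_case_families: int = 74
    n_control_families: int = 80
    dyad_fraction_case: float = 18 / 74
    dyad_fraction_control: float = 2 / 80
    loci: tuple[tuple[Locus, float], ...] = STUDY_PANEL
    maternal_effects: tuple[Effect, ...] = ()
    fetal_effects: tuple[Effect, ...] = ()
    combo_effect: ComboEffect | None = None
    transmission_distortion: float = 0.5   # tau, P(het parent transmits minor)
    prevalence: float = 0.05               # baseline disease probability
    seed: int = 0
    max_draws: int = 4_000_000             # cap on rejection-sampling draws

    def __post_init__(self) -> None:
        for name in ("dyad_fraction_case", "dyad_fraction_control"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.transmission_distortion < 1.0:
            raise ValidationError("transmission_distortion must be in (0, 1)")
        if not 0.0 < self.prevalence < 1.0:
            raise ValidationError("prevalence must be in (0, 1)")
        for _, q in self.loci:
            if not 0.0 < q < 1.0:
                raise ValidationError(f"minor-allele frequency must be in (0, 1), got {q}")
        for eff in (*self.maternal_effects, *self.fetal_effects):
            if eff.odds <= 0:
                raise ValidationError("effect odds must be positive")
        if self.combo_effect is not None and self.combo_effect.odds <= 0:
            raise ValidationError("combo effect odds must be positive")

    def locus_index(self) -> dict[str, int]:
        return {locus.rsid: i for i, (locus, _) in enumerate(self.loci)}


def _in_risk_class(k: np.ndarray, model: str) -> np.ndarray:
    if model == "dominant":
        return k >= 1
    if model == "recessive":
        return k == 2
    raise ValidationError(f"model must be dominant|recessive, got {model!r}")


def _draw_batch(params: SimParams, rng: np.random.Generator, size: int):
    """Vectorised draw of `size` families; returns genotype codes and status."""
    L = len(params.loci)
    tau = params.transmission_distortion
    mother_k = np.empty((size, L), dtype=np.int8)
    father_k = np.empty((size, L), dtype=np.int8)
    child_k = np.empty((size, L), dtype=np.int8)
    for j, (_, q) in enumerate(params.loci):
        m1 = rng.random(size) < q
        m2 = rng.random(size) < q
        f1 = rng.random(size) < q
        f2 = rng.random(size) < q
        # transmitted allele: forced for homozygotes, Bernoulli(tau) for hets
        m_het = m1 != m2
        f_het = f1 != f2
        cm = np.where(m_het, rng.random(size) < tau, m1)
        cf = np.where(f_het, rng.random(size) < tau, f1)
        mother_k[:, j] = m1.astype(np.int8) + m2.astype(np.int8)
        father_k[:, j] = f1.astype(np.int8) + f2.astype(np.int8)
        child_k[:, j] = cm.astype(np.int8) + cf.astype(np.int8)

    idx = params.locus_index()
    eta = np.full(size, logit(params.prevalence))
    for eff in params.maternal_effects:
        eta += math.log(eff.odds) * _in_risk_class(
            mother_k[:, idx[eff.rsid]], eff.model)
    for eff in params.fetal_effects:
        eta += math.log(eff.odds) * _in_risk_class(
            child_k[:, idx[eff.rsid]], eff.model)
    if params.combo_effect is not None:
        ce = params.combo_effect
        m_in = _in_risk_class(mother_k[:, idx[ce.maternal_rsid]],
                              ce.maternal_model) == ce.maternal_risk
        f_in = _in_risk_class(child_k[:, idx[ce.fetal_rsid]],
                              ce.fetal_model) == ce.fetal_risk
        eta += math.log(ce.odds) * (m_in & f_in)
    is_case = rng.random(size) < expit(eta)
    return mother_k, father_k, child_k, is_case


_GT_CACHE: dict[tuple[str, str], tuple] = {}


def _codes_to_genotypes(k_row: np.ndarray, loci) -> dict[str, tuple]:
    genos = {}
    for (locus, _), k in zip(loci, k_row):
        key = (locus.major, locus.minor)
        triple = _GT_CACHE.get(key)
        if triple is None:
            triple = (genotype(locus.major, locus.major),
                      genotype(locus.major, locus.minor),
                      genotype(locus.minor, locus.minor))
            _GT_CACHE[key] = triple
        genos[locus.rsid] = triple[k]
    return genos


def simulate_cohort(params: SimParams,
                    rng: np.random.Generator | None = None) -> Cohort:
    """Simulate one cohort under ``params``.

    Families are drawn until each arm reaches its requested size (rejection
    sampling against the logistic disease model), then the configured
    fraction of fathers per arm is removed.  Identical ``params.seed``
    (with ``rng=None``) reproduces an identical cohort.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    need = {"case": params.n_case_families, "control": params.n_control_families}
    pools: dict[str, list] = {"case": [], "control": []}
    drawn = 0
    while len(pools["case"]) < need["case"] or len(pools["control"]) < need["control"]:
        # rough sizing of the next batch from the baseline acceptance rates
        short_case = need["case"] - len(pools["case"])
        short_ctrl = need["control"] - len(pools["control"])
        est = (short_case / max(params.prevalence, 1e-3)
               + short_ctrl / max(1.0 - params.prevalence, 1e-3))
        size = int(min(max(128, 1.3 * est), 65536))
        if drawn + size > params.max_draws:
            raise SimulationError(
                f"draw cap {params.max_draws} exceeded; the requested case "
                "prevalence appears unreachable under these parameters")
        drawn += size
        mk, fk, ck, is_case = _draw_batch(params, rng, size)
        for i in range(size):
            status = "case" if is_case[i] else "control"
            if len(pools[status]) < need[status]:
                pools[status].append((mk[i], fk[i], ck[i]))

    families: list[Family] = []
    for status, prefix, frac in (("case", "case", params.dyad_fraction_case),
                                 ("control", "ctrl", params.dyad_fraction_control)):
        n = need[status]
        n_dyads = int(round(frac * n))
        dyad_idx = set(rng.choice(n, size=n_dyads, replace=False)) if n_dyads else set()
        for i, (mk_row, fk_row, ck_row) in enumerate(pools[status]):
            families.append(Family(
                family_id=f"{prefix}{i + 1:04d}",
                status=status,
                mother=_codes_to_genotypes(mk_row, params.loci),
                offspring=_codes_to_genotypes(ck_row, params.loci),
                father=(None if i in dyad_idx
                        else _codes_to_genotypes(fk_row, params.loci)),
            ))
    return Cohort(loci=[locus for locus, _ in params.loci], families=families)


@dataclass(frozen=True)
class TestSpec:
    """Names one pipeline test for power estimation.

    kind='allelic'   : allelic case-control test at ``rsid`` for ``role``.
    kind='genotypic' : collapsed genotype test (``model``) at ``rsid``.
    kind='tdt'       : TDT at ``rsid`` in ``status`` triads, ``stratum``.
    kind='combo'     : maternal (``rsid``) x fetal (``fetal_rsid``) table;
                       global test, or the Wald test of ``category`` vs the
                       auto-selected reference.
    """

    __test__ = False  # not a test class, despite the name

    kind: str
    rsid: str
    role: str = "offspring"
    model: str | None = "dominant"
    status: str = "case"
    stratum: str = "all"
    fetal_rsid: str | None = None
    maternal_model: str = "dominant"
    fetal_model: str = "dominant"
    category: str | None = None


def _p_value(cohort: Cohort, spec: TestSpec) -> float:
    from .assoc import AllelicAssociation, GenotypicAssociation
    from .joint import MaternalFetalCombination
    from .tdt import TransmissionDisequilibriumTest

    if spec.kind == "allelic":
        return AllelicAssociation(cohort, spec.rsid, spec.role).fit(
            test="pearson").result.p_value
    if spec.kind == "genotypic":
        return GenotypicAssociation(cohort, spec.rsid, spec.role,
                                    model=spec.model).fit(
            test="pearson").result.p_value
    if spec.kind == "tdt":
        res = TransmissionDisequilibriumTest(
            cohort, spec.rsid, spec.status).fit()
        p = res.strata[spec.stratum].p_value
        return 1.0 if p is None else p
    if spec.kind == "combo":
        fitted = MaternalFetalCombination(
            cohort, spec.rsid, spec.fetal_rsid,
            maternal_model=spec.maternal_model,
            fetal_model=spec.fetal_model).fit()
        if spec.category is None:
            return fitted.global_test.p_value
        r = fitted.category_ors[spec.category]
        return 1.0 if r is None else r.p_value
    raise ValidationError(f"unknown test kind {spec.kind!r}")


@dataclass
class PowerEstimate:
    """Monte-Carlo power estimate with its binomial uncertainty."""

    power: float
    se: float
    ci_low: float
    ci_high: float
    n_reps: int
    n_rejected: int
    alpha: float
    low_reps_warning: bool = False

    def __str__(self) -> str:
        warn = "  [warning: < 100 replicates]" if self.low_reps_warning else ""
        return (f"power = {self.power:.3f} +/- {self.se:.3f} "
                f"(95% CI {self.ci_low:.3f}-{self.ci_high:.3f}; "
                f"{self.n_rejected}/{self.n_reps} rejections at "
                f"alpha={self.alpha}){warn}")


def estimate_power(params: SimParams, test_spec: TestSpec,
                   n_reps: int = 1000, alpha: float = 0.05,
                   seed: int | None = None,
                   statistic: Callable[[Cohort], float] | None = None,
                   ) -> PowerEstimate:
    """Fraction of simulated replicates in which the named test rejects.

    ``seed`` (default: ``params.seed``) seeds a replicate-spawning stream,
    so each replicate gets an independent substream.  ``statistic``
    optionally replaces the named test with a custom p-value function.
    """
    base = np.random.SeedSequence(params.seed if seed is None else seed)
    n_rejected = 0
    for child in base.spawn(n_reps):
        cohort = simulate_cohort(params, rng=np.random.default_rng(child))
        p = (statistic(cohort) if statistic is not None
             else _p_value(cohort, test_spec))
        if p < alpha:
            n_rejected += 1
    power = n_rejected / n_reps
    se = math.sqrt(power * (1 - power) / n_reps)
    return PowerEstimate(
        power=power, se=se,
        ci_low=max(0.0, power - 1.96 * se),
        ci_high=min(1.0, power + 1.96 * se),
        n_reps=n_reps, n_rejected=n_rejected, alpha=alpha,
        low_reps_warning=n_reps < 100)
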