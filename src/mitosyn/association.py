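"""Carriership 2x2 tables, Fisher exact P, odds ratio with Woolf CI.

Features come in three kinds, all scored as carriership (dominant coding
for alleles): carrying a mitochondrial haplogroup, carrying at least one
copy of a nuclear allele, or matching an exact unordered nuclear genotype.
Each feature yields a case/control x carrier/non-carrier table over the
subjects informative for that feature (complete-case), from which the
two-sided Fisher exact P, the cross-product odds ratio and the Woolf
log-normal confidence interval are computed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .cohort import CohortTable, SubjectRecord
from .errors import ConfigError, DegenerateTableError, FeatureError
from .haplogroups import HaplogroupCall, call_cohort

_TIE_RTOL = 1e-12


class FeatureKind(enum.Enum):
    HAPLOGROUP = "haplogroup"
    ALLELE_CARRIER = "allele"
    GENOTYPE_CARRIER = "genotype"


class Carrier(enum.Enum):
    CARRIER = "carrier"
    NONCARRIER = "noncarrier"
    MISSING = "missing"


@dataclass(frozen=True)
class Feature:
    """One scoreable genetic feature.

    ``locus`` is an rsID for nuclear features and ``"mtDNA"`` for
    haplogroups; ``value`` is the haplogroup label, the carried allele, or
    the exact genotype pair.
    """

    kind: FeatureKind
    locus: str
    value: str | tuple[str, str]

    @classmethod
    def haplogroup(cls, label: str) -> "Feature":
        return cls(FeatureKind.HAPLOGROUP, "mtDNA", label)

    @classmethod
    def allele(cls, locus: str, allele: str) -> "Feature":
        return cls(FeatureKind.ALLELE_CARRIER, locus, allele)

    @classmethod
    def genotype(cls, locus: str, a: str, b: str) -> "Feature":
        return cls(FeatureKind.GENOTYPE_CARRIER, locus, tuple(sorted((a, b))))

    @classmethod
    def parse(cls, text: str) -> "Feature":
        """Parse ``hg:J``, ``rs2107538:A`` or ``rs1640923:A/A``."""
        locus, sep, value = text.partition(":")
        if not sep or not value:
            raise ConfigError(f"cannot parse feature {text!r}")
        if locus == "hg":
            return cls.haplogroup(value)
        if "/" in value:
            a, _, b = value.partition("/")
            return cls.genotype(locus, a, b)
        return cls.allele(locus, value)

    @property
    def name(self) -> str:
        if self.kind is FeatureKind.HAPLOGROUP:
            return f"Haplogroup {self.value}"
        if self.kind is FeatureKind.GENOTYPE_CARRIER:
            return f"{self.locus}*{'/'.join(self.value)}"
        return f"{self.locus}*{self.value}"


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts a..d: case-carriers, case-noncarriers, control-carriers,
    control-noncarriers."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def n_case(self) -> int:
        return self.a + self.b

    @property
    def n_control(self) -> int:
        return self.c + self.d

    def swapped_columns(self) -> "TwoByTwoTable":
        return TwoByTwoTable(self.b, self.a, self.d, self.c)

    def swapped_rows(self) -> "TwoByTwoTable":
        return TwoByTwoTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class AssociationResult:
    feature: str
    table: TwoByTwoTable
    freq_case_pct: float
    freq_control_pct: float
    p: float
    or_value: float
    ci_low: float
    ci_high: float
    correction_applied: bool

    def to_row(self) -> dict:
        t = self.table
        return {
            "feature": self.feature,
            "n_case_carrier": t.a,
            "n_case_total": t.n_case,
            "n_control_carrier": t.c,
            "n_control_total": t.n_control,
            "freq_case_pct": self.freq_case_pct,
            "freq_control_pct": self.freq_control_pct,
            "p_fisher": self.p,
            "odds_ratio": self.or_value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "correction_applied": self.correction_applied,
        }


def carrier_status(
    subject: SubjectRecord,
    feature: Feature,
    calls: dict[str, HaplogroupCall] | None = None,
) -> Carrier:
    """Score one subject for one feature.

    Haplogroup features: CARRIER iff the subject's call equals the label,
    MISSING iff the call is UNKNOWN. Allele features: CARRIER iff the
    allele appears in the genotype (dominant). Genotype features: CARRIER
    iff the exact unordered genotype matches. A missing genotype scores
    MISSING.
    """
    if feature.kind is FeatureKind.HAPLOGROUP:
        if calls is not None:
            call = calls[subject.subject_id]
        else:
            from .haplogroups import call_haplogroup

            call = call_haplogroup(subject.mt)
        if not call.known:
            return Carrier.MISSING
        return (
            Carrier.CARRIER if call.label == feature.value else Carrier.NONCARRIER
        )
    genotype = subject.nuclear.get(feature.locus)
    if genotype is None:
        raise FeatureError(f"locus {feature.locus!r} not in cohort registry")
    if genotype.is_missing:
        return Carrier.MISSING
    if feature.kind is FeatureKind.ALLELE_CARRIER:
        carries = genotype.carries(feature.value)
    else:
        carries = genotype.matches(feature.value)
    return Carrier.CARRIER if carries else Carrier.NONCARRIER


def build_2x2(
    cohort: CohortTable,
    feature: Feature,
    calls: dict[str, HaplogroupCall] | None = None,
) -> TwoByTwoTable:
    """Carriership table over informative subjects (complete-case)."""
    if (
        feature.kind is not FeatureKind.HAPLOGROUP
        and feature.locus not in cohort.locus_registry
    ):
        raise FeatureError(f"locus {feature.locus!r} not in cohort registry")
    if calls is None and feature.kind is FeatureKind.HAPLOGROUP:
        calls = call_cohort(cohort)
    a = b = c = d = 0
    for s in cohort:
        st = carrier_status(s, feature, calls)
        if st is Carrier.MISSING:
            continue
        if s.is_case:
            if st is Carrier.CARRIER:
                a += 1
            else:
                b += 1
        else:
            if st is Carrier.CARRIER:
                c += 1
            else:
                d += 1
    if a + b == 0 or c + d == 0:
        raise DegenerateTableError(
            f"no informative subjects in one status group for {feature.name}"
        )
    return TwoByTwoTable(a, b, c, d)


def fisher_two_sided(t: TwoByTwoTable) -> float:
    """Two-sided Fisher exact P by probability ordering.

    Sums hypergeometric point probabilities over all tables with the
    observed margins whose probability does not exceed the observed one
    (relative tie tolerance 1e-12).
    """
    n1, n2 = t.n_case, t.n_control
    k = t.a + t.c
    if n1 == 0 or n2 == 0 or k + t.b + t.d == 0:
        raise DegenerateTableError("degenerate margins for Fisher test")
    n = n1 + n2
    lo = max(0, k - n2)
    hi = min(k, n1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, k, n1)
    p_obs = pmf[t.a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum())
    return min(1.0, p)


def odds_ratio_woolf(
    t: TwoByTwoTable, z: float = 1.96
) -> tuple[float, float, float, bool]:
    """Cross-product OR with Woolf log-normal CI.

    If any cell is zero, 0.5 is added to all four cells first
    (Haldane-Anscombe) and the correction flag is set.
    """
    if t.n_case == 0 or t.n_control == 0:
        raise DegenerateTableError("empty status margin")
    cells = [float(t.a), float(t.b), float(t.c), float(t.d)]
    correction = min(cells) == 0
    if correction:
        cells = [x + 0.5 for x in cells]
    a, b, c, d = cells
    or_value = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = math.exp(math.log(or_value) - z * se)
    ci_high = math.exp(math.log(or_value) + z * se)
    return or_value, ci_low, ci_high, correction


def associate(
    cohort: CohortTable,
    feature: Feature,
    calls: dict[str, HaplogroupCall] | None = None,
    z: float = 1.96,
) -> AssociationResult:
    """Full association summary for one feature."""
    t = build_2x2(cohort, feature, calls)
    p = fisher_two_sided(t)
    or_value, ci_low, ci_high, corr = odds_ratio_woolf(t, z=z)
    return AssociationResult(
        feature=feature.name,
        table=t,
        freq_case_pct=100.0 * t.a / t.n_case,
        freq_control_pct=100.0 * t.c / t.n_control,
        p=p,
        or_value=or_value,
        ci_low=ci_low,
        ci_high=ci_high,
        correction_applied=corr,
    )


def stratify_by_sex(cohort: CohortTable) -> tuple[CohortTable, CohortTable]:
    """Partition into (female, male) strata; missing-sex subjects in neither."""
    female = cohort.subset(lambda s: s.sex == "F")
    male = cohort.subset(lambda s: s.sex == "M")
    return female, male
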