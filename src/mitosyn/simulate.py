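"""Synthetic case-control cohorts with configurable marginal and synergistic
effects, plus exact reconstructions of the study's aggregate tables.

The generative model is a retrospective (case-control) design over two
binary exposures: factor A (mitochondrial haplogroup J carriage) and
factor B (carriage of a nuclear allele or genotype). Exposure strata
(i, j) have population probabilities from independent carriage with
frequencies ``p_a_pop`` and ``p_b_pop``, and disease odds

    odds(i, j) = baseline_odds * or10**i * or01**j * sf**(i*j)

so ``or10``/``or01`` are the single-exposure odds ratios against
double-non-carriers and ``sf`` is the synergy factor. Case and control
stratum distributions follow by Bayes' rule, and the requested numbers of
cases and controls are drawn multinomially from them — exact and fast,
and it matches how odds ratios (not risks) are the estimand under
retrospective sampling.

Factor A is realized as the J-defining five-marker haplotype; non-carriers
draw a background haplogroup pattern. Factor B is realized as a nuclear
genotype: carriers are heterozygous with probability ``het_fraction``,
otherwise homozygous for the risk allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortTable, MtMarkerSet, NuclearGenotype, SubjectRecord, Status
from .epistasis import TwoByTwoByTwoTable, reconstruct_from_marginals
from .errors import ConfigError
from .haplogroups import HAPLOGROUP_PATTERNS

# A non-H/J/K/U pattern for the OTHER background class (1719A excludes all
# four defined haplogroups).
_OTHER_PATTERN = ("A", "C", "G", "A", "A")

# Background haplogroup mix among factor-A non-carriers. H dominates, as in
# European-ancestry control samples; exact values are configuration, not
# estimates.
DEFAULT_BACKGROUND_HG = {"H": 0.55, "K": 0.10, "U": 0.20, "OTHER": 0.15}


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic cohort.

    Defaults mirror the study conditions for the haplogroup-J x CCL5
    rs2107538*A pair: carrier frequencies near the control margins
    (p_a 0.10, p_b 0.37), single-exposure odds ratios 1.25 and 0.97,
    synergy factor 4.3, and a rare-disease baseline odds of 0.01.
    ``het_fraction`` 0.88 is the Hardy-Weinberg heterozygote share among
    carriers at the default carrier frequency.
    """

    n_case: int = 283
    n_control: int = 290
    p_a_pop: float = 0.10
    p_b_pop: float = 0.37
    or10: float = 1.25
    or01: float = 0.97
    sf: float = 4.3
    baseline_odds: float = 0.01
    het_fraction: float = 0.88
    background_hg: dict = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_HG)
    )
    locus: str = "rs2107538"
    risk_allele: str = "A"
    other_allele: str = "G"
    female_fraction_case: float = 198 / 283
    female_fraction_control: float = 197 / 290
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_a_pop", "p_b_pop", "het_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("or10", "or01", "sf", "baseline_odds"):
            v = getattr(self, name)
            if not (v > 0 and np.isfinite(v)):
                raise ConfigError(f"{name} must be a positive finite number")
        if self.n_case < 1 or self.n_control < 1:
            raise ConfigError("n_case and n_control must be >= 1")
        total = sum(self.background_hg.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"background_hg frequencies must sum to 1, got {total}"
            )
        unknown = set(self.background_hg) - {"H", "K", "U", "OTHER"}
        if unknown:
            raise ConfigError(f"unknown background classes: {sorted(unknown)}")


def stratum_distributions(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Case and control probabilities over strata (11, 10, 01, 00).

    Population stratum frequencies come from independent carriage; the
    case distribution weights each stratum by its disease probability and
    the control distribution by its complement (Bayes' rule).
    """
    pa, pb = cfg.p_a_pop, cfg.p_b_pop
    q = np.array(
        [pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)]
    )
    i = np.array([1, 1, 0, 0])
    j = np.array([1, 0, 1, 0])
    odds = cfg.baseline_odds * cfg.or10**i * cfg.or01**j * cfg.sf ** (i * j)
    if not np.all(np.isfinite(odds)):
        raise ConfigError("non-finite disease odds in some stratum")
    risk = odds / (1.0 + odds)
    case_w = q * risk
    ctrl_w = q * (1.0 - risk)
    if case_w.sum() <= 0 or ctrl_w.sum() <= 0:
        raise ConfigError("degenerate disease model: empty status group")
    return case_w / case_w.sum(), ctrl_w / ctrl_w.sum()


def _mt_pattern(label: str) -> tuple[str, ...]:
    return HAPLOGROUP_PATTERNS.get(label, _OTHER_PATTERN)


def _nuclear_genotype(cfg: SimulationConfig, carrier: bool, het: bool) -> NuclearGenotype:
    if not carrier:
        token = f"{cfg.other_allele}/{cfg.other_allele}"
    elif het:
        token = f"{cfg.risk_allele}/{cfg.other_allele}"
    else:
        token = f"{cfg.risk_allele}/{cfg.risk_allele}"
    return NuclearGenotype.from_token(cfg.locus, token)


def generate_cohort(cfg: SimulationConfig) -> CohortTable:
    """Draw one synthetic cohort; byte-identical for identical config."""
    cfg.validate()
    case_dist, ctrl_dist = stratum_distributions(cfg)
    rng = np.random.default_rng(cfg.seed)
    counts = {
        Status.CASE: rng.multinomial(cfg.n_case, case_dist),
        Status.CONTROL: rng.multinomial(cfg.n_control, ctrl_dist),
    }
    bg_labels = sorted(cfg.background_hg)
    bg_probs = np.array([cfg.background_hg[k] for k in bg_labels])
    female_frac = {
        Status.CASE: cfg.female_fraction_case,
        Status.CONTROL: cfg.female_fraction_control,
    }
    subjects: list[SubjectRecord] = []
    for status in (Status.CASE, Status.CONTROL):
        prefix = "case" if status is Status.CASE else "ctrl"
        n_total = cfg.n_case if status is Status.CASE else cfg.n_control
        strata = np.repeat(np.arange(4), counts[status])
        # per-subject randomness drawn in bulk for reproducibility
        bg_draw = rng.choice(len(bg_labels), size=n_total, p=bg_probs)
        het_draw = rng.random(n_total) < cfg.het_fraction
        sex_draw = rng.random(n_total) < female_frac[status]
        for idx in range(n_total):
            stratum = strata[idx]
            a_carrier = stratum in (0, 1)
            b_carrier = stratum in (0, 2)
            if a_carrier:
                mt = MtMarkerSet.from_tuple(HAPLOGROUP_PATTERNS["J"])
            else:
                mt = MtMarkerSet.from_tuple(_mt_pattern(bg_labels[bg_draw[idx]]))
            genotype = _nuclear_genotype(cfg, b_carrier, bool(het_draw[idx]))
            subjects.append(
                SubjectRecord(
                    subject_id=f"{prefix}{idx + 1:05d}",
                    status=status,
                    sex="F" if sex_draw[idx] else "M",
                    mt=mt,
                    nuclear={cfg.locus: genotype},
                )
            )
    return CohortTable(subjects, [cfg.locus])


# --- Study fixtures -------------------------------------------------------
#
# Aggregate counts of the published case-control sample: 283 cases and 290
# controls; per pair, the haplogroup-J carrier count, the nuclear-feature
# carrier count and the joint-carrier count in each status group.

@dataclass(frozen=True)
class _PairSpec:
    locus: str
    feature_kind: str  # "allele" or "genotype"
    feature_value: str
    other_allele: str
    n_b_case: int
    n_b_ctrl: int
    n_ab_case: int
    n_ab_ctrl: int


N_CASE_STUDY = 283
N_CONTROL_STUDY = 290
N_J_CASE = 45
N_J_CTRL = 25
SEX_SPLIT = {"case": (198, 85), "control": (197, 93)}  # (F, M)

STUDY_PAIRS: dict[str, _PairSpec] = {
    "ccl5": _PairSpec("rs2107538", "allele", "A", "G", 110, 105, 21, 4),
    "pvt1": _PairSpec("rs2114358", "allele", "G", "A", 169, 170, 35, 14),
    "tnfsf14": _PairSpec("rs1077667", "allele", "C", "T", 266, 261, 44, 21),
    "il4": _PairSpec("rs2243250", "allele", "C", "T", 267, 264, 44, 21),
    "clec16a": _PairSpec("rs1640923", "genotype", "A/A", "G", 221, 203, 39, 17),
}


def study_table(pair: str) -> TwoByTwoByTwoTable:
    """The pair's reconstructed 2x2x2 table (inclusion-exclusion)."""
    spec = _pair_spec(pair)
    return reconstruct_from_marginals(
        N_J_CASE,
        spec.n_b_case,
        spec.n_ab_case,
        N_CASE_STUDY,
        N_J_CTRL,
        spec.n_b_ctrl,
        spec.n_ab_ctrl,
        N_CONTROL_STUDY,
    )


def _pair_spec(pair: str) -> _PairSpec:
    try:
        return STUDY_PAIRS[pair.lower()]
    except KeyError:
        raise ConfigError(
            f"unknown study pair {pair!r}; choose from {sorted(STUDY_PAIRS)}"
        ) from None


def study_feature(pair: str):
    """The nuclear feature of one study pair, as an association Feature."""
    from .association import Feature

    spec = _pair_spec(pair)
    if spec.feature_kind == "genotype":
        a, b = spec.feature_value.split("/")
        return Feature.genotype(spec.locus, a, b)
    return Feature.allele(spec.locus, spec.feature_value)


def study_fixture(pair: str) -> CohortTable:
    """Individual-level cohort exactly reproducing one pair's aggregates.

    Emits 283 cases and 290 controls whose haplogroup-J carriage,
    nuclear-feature carriage and joint carriage match the published
    counts. Sex follows the 198/85 (cases) and 197/93 (controls) splits,
    assigned deterministically and independently of genotype — joint
    sex x genotype counts were not published, so sex-stratified results
    on fixtures are conventional, not reconstructions.
    """
    spec = _pair_spec(pair)
    table = study_table(pair)
    j_pattern = HAPLOGROUP_PATTERNS["J"]
    h_pattern = HAPLOGROUP_PATTERNS["H"]

    if spec.feature_kind == "genotype":
        a, _ = spec.feature_value.split("/")
        carrier_token = spec.feature_value
        noncarrier_token = f"{a}/{spec.other_allele}"
    else:
        carrier_token = f"{spec.feature_value}/{spec.other_allele}"
        noncarrier_token = f"{spec.other_allele}/{spec.other_allele}"

    subjects: list[SubjectRecord] = []
    for status, cells, total in (
        (Status.CASE, table.case, N_CASE_STUDY),
        (Status.CONTROL, table.control, N_CONTROL_STUDY),
    ):
        n_f, n_m = SEX_SPLIT[status.value]
        assert n_f + n_m == total
        prefix = "case" if status is Status.CASE else "ctrl"
        k = 0
        for cell, (a_carrier, b_carrier) in zip(
            cells, ((True, True), (True, False), (False, True), (False, False))
        ):
            for _ in range(cell):
                mt = MtMarkerSet.from_tuple(
                    j_pattern if a_carrier else h_pattern
                )
                token = carrier_token if b_carrier else noncarrier_token
                subjects.append(
                    SubjectRecord(
                        subject_id=f"{prefix}{k + 1:04d}",
                        status=status,
                        sex="F" if k < n_f else "M",
                        mt=mt,
                        nuclear={
                            spec.locus: NuclearGenotype.from_token(
                                spec.locus, token
                            )
                        },
                    )
                )
                k += 1
    return CohortTable(subjects, [spec.locus])
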