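"""Exhaustive mining of feature combinations (haplogroup x nuclear carriership).

Every subset of 1..max_order features on distinct loci is scored as a joint
carriership: a subject is a joint carrier iff it carries ALL component
features, and uninformative for the combination iff any component is
missing. Each combination's 2x2 table goes through the same Fisher/OR/Woolf
machinery as single features. The enumeration is exact — it replaces a
stochastic search over the same hypothesis space, which at this problem
size (a handful of haplogroups times tens of nuclear features, order <= 2)
is only a few thousand tables.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .association import (
    AssociationResult,
    Carrier,
    Feature,
    TwoByTwoTable,
    carrier_status,
    fisher_two_sided,
    odds_ratio_woolf,
)
from .cohort import CohortTable
from .errors import ConfigError, DegenerateTableError
from .haplogroups import call_cohort


@dataclass(frozen=True)
class Combination:
    """A set of 1..k features on distinct loci, scored jointly."""

    features: tuple[Feature, ...]

    def __post_init__(self) -> None:
        loci = [f.locus for f in self.features]
        if len(set(loci)) != len(loci):
            raise ConfigError(
                "combination features must reference distinct loci"
            )

    @property
    def name(self) -> str:
        return " + ".join(f.name for f in sorted_features(self.features))

    @property
    def order(self) -> int:
        return len(self.features)


def sorted_features(features) -> list[Feature]:
    return sorted(features, key=lambda f: f.name)


def joint_carrier_status(subject, combo: Combination, calls) -> Carrier:
    """CARRIER iff all components carried; MISSING if any component missing."""
    result = Carrier.CARRIER
    for f in combo.features:
        st = carrier_status(subject, f, calls)
        if st is Carrier.MISSING:
            return Carrier.MISSING
        if st is Carrier.NONCARRIER:
            result = Carrier.NONCARRIER
    return result


def build_joint_2x2(
    cohort: CohortTable, combo: Combination, calls=None
) -> TwoByTwoTable:
    if calls is None:
        calls = call_cohort(cohort)
    a = b = c = d = 0
    for s in cohort:
        st = joint_carrier_status(s, combo, calls)
        if st is Carrier.MISSING:
            continue
        if s.is_case:
            a, b = (a + 1, b) if st is Carrier.CARRIER else (a, b + 1)
        else:
            c, d = (c + 1, d) if st is Carrier.CARRIER else (c, d + 1)
    if a + b == 0 or c + d == 0:
        raise DegenerateTableError(
            f"no informative subjects in one status group for {combo.name}"
        )
    return TwoByTwoTable(a, b, c, d)


@dataclass(frozen=True)
class CombinationResult:
    combination: Combination
    result: AssociationResult
    significant: bool
    stronger_than_components: bool
    p_adjusted: float | None = None

    def to_row(self) -> dict:
        row = {"combination": self.combination.name, "order": self.combination.order}
        row.update(self.result.to_row())
        del row["feature"]
        row["significant"] = self.significant
        row["stronger_than_components"] = self.stronger_than_components
        if self.p_adjusted is not None:
            row["p_adjusted"] = self.p_adjusted
        return row


@dataclass
class MiningReport:
    results: list[CombinationResult] = field(default_factory=list)
    alpha: float = 0.05
    adjust: str = "none"

    def __iter__(self):
        return iter(self.results)

    def __len__(self):
        return len(self.results)

    def significant_results(self) -> list[CombinationResult]:
        return [r for r in self.results if r.significant]

    def to_rows(self) -> list[dict]:
        return [r.to_row() for r in self.results]


def _benjamini_hochberg(pvalues: list[float]) -> list[float]:
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_top, idx in enumerate(reversed(order)):
        rank = m - rank_from_top
        running = min(running, pvalues[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


def enumerate_combinations(
    cohort: CohortTable,
    features: list[Feature],
    max_order: int = 2,
    alpha: float = 0.05,
    adjust: str = "none",
) -> MiningReport:
    """Score every size-1..max_order feature subset with distinct loci.

    Output order is deterministic: descending ``|ln OR|``, ties broken
    lexicographically by combination name. ``significant`` requires both
    P < alpha and the OR CI excluding 1; ``stronger_than_components``
    flags combinations whose P is lower than every component feature's P.
    Combinations whose joint table is degenerate (e.g. nobody informative)
    are skipped. ``adjust="bh"`` adds Benjamini-Hochberg adjusted P values
    (reported, never used for the significance flag).
    """
    if max_order < 1:
        raise ConfigError("max_order must be >= 1")
    if not features:
        raise ConfigError("feature list is empty")
    n_loci = len({f.locus for f in features})
    if max_order > n_loci:
        raise ConfigError(
            f"max_order {max_order} exceeds the {n_loci} distinct loci available"
        )
    calls = call_cohort(cohort)

    single_p: dict[Feature, float] = {}
    scored: list[tuple[Combination, AssociationResult]] = []
    for order in range(1, max_order + 1):
        for subset in itertools.combinations(features, order):
            if len({f.locus for f in subset}) != order:
                continue  # two features at one locus: different hypothesis
            combo = Combination(tuple(subset))
            try:
                t = build_joint_2x2(cohort, combo, calls)
            except DegenerateTableError:
                continue
            p = fisher_two_sided(t)
            or_value, ci_low, ci_high, corr = odds_ratio_woolf(t)
            res = AssociationResult(
                feature=combo.name,
                table=t,
                freq_case_pct=100.0 * t.a / t.n_case,
                freq_control_pct=100.0 * t.c / t.n_control,
                p=p,
                or_value=or_value,
                ci_low=ci_low,
                ci_high=ci_high,
                correction_applied=corr,
            )
            if order == 1:
                single_p[subset[0]] = p
            scored.append((combo, res))

    scored.sort(key=lambda cr: (-abs(math.log(cr[1].or_value)), cr[0].name))
    adjusted = (
        _benjamini_hochberg([r.p for _, r in scored])
        if adjust == "bh"
        else [None] * len(scored)
    )
    results = []
    for (combo, res), p_adj in zip(scored, adjusted):
        significant = res.p < alpha and (res.ci_low > 1.0 or res.ci_high < 1.0)
        stronger = combo.order > 1 and all(
            res.p < single_p[f] for f in combo.features if f in single_p
        )
        results.append(
            CombinationResult(combo, res, significant, stronger, p_adj)
        )
    return MiningReport(results, alpha=alpha, adjust=adjust)


def permutation_validate(
    cohort: CohortTable,
    combination: Combination,
    n_perm: int,
    seed: int,
) -> float:
    """Empirical P for one combination by case/control label shuffling.

    The fraction of permuted cohorts whose joint-carriership Fisher P is
    at most the observed P, with add-one smoothing ``(hits+1)/(n_perm+1)``.
    Reproducible given ``seed``.
    """
    if n_perm < 100:
        raise ConfigError("n_perm must be >= 100")
    calls = call_cohort(cohort)
    statuses: list[bool] = []
    carriers: list[bool] = []
    for s in cohort:
        st = joint_carrier_status(s, combination, calls)
        if st is Carrier.MISSING:
            continue
        statuses.append(s.is_case)
        carriers.append(st is Carrier.CARRIER)
    status_arr = np.array(statuses)
    carrier_arr = np.array(carriers)
    n_case = int(status_arr.sum())
    n_control = len(status_arr) - n_case
    if n_case == 0 or n_control == 0:
        raise DegenerateTableError("degenerate observed table for permutation")
    observed = fisher_two_sided(_table_from_vectors(status_arr, carrier_arr))
    rng = np.random.default_rng(seed)
    hits = 0
    perm = status_arr.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        p = fisher_two_sided(_table_from_vectors(perm, carrier_arr))
        if p <= observed:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def _table_from_vectors(status: np.ndarray, carrier: np.ndarray) -> TwoByTwoTable:
    a = int((status & carrier).sum())
    b = int((status & ~carrier).sum())
    c = int((~status & carrier).sum())
    d = int((~status & ~carrier).sum())
    return TwoByTwoTable(a, b, c, d)
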