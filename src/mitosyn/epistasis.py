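"""Two-factor epistasis in case-control data: synergy factor and exact
three-way interaction test.

Both statistics operate on a disease x factor-A x factor-B table of eight
counts. With double-non-carriers as the reference exposure stratum, the
three stratum odds ratios are

    OR11 = (case[1,1]/case[0,0]) / (ctrl[1,1]/ctrl[0,0])
    OR10 = (case[1,0]/case[0,0]) / (ctrl[1,0]/ctrl[0,0])
    OR01 = (case[0,1]/case[0,0]) / (ctrl[0,1]/ctrl[0,0])

and the synergy factor is SF = OR11 / (OR10 * OR01): the factor by which
the joint-exposure odds ratio exceeds the product of the single-exposure
odds ratios. SF = 1 is the multiplicative null; SF > 1 indicates positive
(synergistic) epistasis. The CI is log-normal with
Var(ln SF) = sum of reciprocals of the eight working cells.

The exact interaction test (FLINT) conditions on all three two-way margins
(status x A, status x B, A x B). The family of 2x2x2 tables with those
margins has a single degree of freedom, indexed by the pivot cell
case[1,1]; under the null of no three-way interaction each feasible table
has probability proportional to 1 / prod(cell!) over the eight cells. The
two-sided P is the total null probability of tables no more probable than
the observed one (probability ordering), computed in log-factorial
arithmetic.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .association import Carrier, Feature, carrier_status
from .cohort import CohortTable
from .errors import (
    DegenerateTableError,
    InconsistentMarginalsError,
)
from .haplogroups import call_cohort

_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class TwoByTwoByTwoTable:
    """Eight counts n[status][i][j], i = factor-A carriage, j = factor-B.

    ``case`` and ``control`` each hold (n11, n10, n01, n00).
    """

    case: tuple[int, int, int, int]
    control: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if min(self.case) < 0 or min(self.control) < 0:
            raise ValueError("negative cell count")

    @property
    def n_case(self) -> int:
        return sum(self.case)

    @property
    def n_control(self) -> int:
        return sum(self.control)

    def cells(self) -> np.ndarray:
        """Array of shape (2, 2, 2): [status, A, B] with index 0 = carrier."""
        c = self.case
        k = self.control
        return np.array(
            [[[c[0], c[1]], [c[2], c[3]]], [[k[0], k[1]], [k[2], k[3]]]],
            dtype=float,
        )

    def swapped_factors(self) -> "TwoByTwoByTwoTable":
        c = self.case
        k = self.control
        return TwoByTwoByTwoTable(
            (c[0], c[2], c[1], c[3]), (k[0], k[2], k[1], k[3])
        )

    def swapped_status(self) -> "TwoByTwoByTwoTable":
        return TwoByTwoByTwoTable(self.control, self.case)


@dataclass(frozen=True)
class SynergyResult:
    sf: float
    ln_sf_se: float
    ci_low: float
    ci_high: float
    correction_applied: bool
    or11: float
    or10: float
    or01: float

    @property
    def ci_excludes_one(self) -> bool:
        return self.ci_low > 1.0 or self.ci_high < 1.0


@dataclass(frozen=True)
class FlintResult:
    p_flint: float
    n_tables: int
    free_range: tuple[int, int]
    p_synergy: float  # one-sided: pivot >= observed


class InteractionCall(enum.Enum):
    EPISTATIC = "epistatic"
    SUGGESTIVE = "suggestive"
    NOT_SUPPORTED = "not_supported"


def build_2x2x2(
    cohort: CohortTable,
    feat_a: Feature,
    feat_b: Feature,
    calls=None,
) -> TwoByTwoByTwoTable:
    """Joint exposure table, complete-case over both features."""
    if feat_a.locus == feat_b.locus:
        raise InconsistentMarginalsError(
            "epistasis factors must be on distinct loci"
        )
    if calls is None:
        calls = call_cohort(cohort)
    counts = {True: [0, 0, 0, 0], False: [0, 0, 0, 0]}
    for s in cohort:
        sa = carrier_status(s, feat_a, calls)
        sb = carrier_status(s, feat_b, calls)
        if sa is Carrier.MISSING or sb is Carrier.MISSING:
            continue
        i = sa is Carrier.CARRIER
        j = sb is Carrier.CARRIER
        idx = {(True, True): 0, (True, False): 1, (False, True): 2,
               (False, False): 3}[(i, j)]
        counts[s.is_case][idx] += 1
    if sum(counts[True]) == 0 or sum(counts[False]) == 0:
        raise DegenerateTableError(
            "no informative subjects in one status group"
        )
    return TwoByTwoByTwoTable(tuple(counts[True]), tuple(counts[False]))


def reconstruct_from_marginals(
    n_a_case: int,
    n_b_case: int,
    n_ab_case: int,
    n_case: int,
    n_a_ctrl: int,
    n_b_ctrl: int,
    n_ab_ctrl: int,
    n_ctrl: int,
) -> TwoByTwoByTwoTable:
    """Recover the eight exposure-stratum counts from marginal carrier
    counts and the joint-carrier count, per status, by inclusion-exclusion:

        n11 = nAB, n10 = nA - nAB, n01 = nB - nAB, n00 = N - nA - nB + nAB
    """

    def strata(na: int, nb: int, nab: int, n: int, label: str):
        if nab > min(na, nb):
            raise InconsistentMarginalsError(
                f"{label}: joint count {nab} exceeds a marginal ({na}, {nb})"
            )
        n00 = n - na - nb + nab
        if n00 < 0:
            raise InconsistentMarginalsError(
                f"{label}: marginals exceed total ({na} + {nb} - {nab} > {n})"
            )
        return (nab, na - nab, nb - nab, n00)

    return TwoByTwoByTwoTable(
        strata(n_a_case, n_b_case, n_ab_case, n_case, "cases"),
        strata(n_a_ctrl, n_b_ctrl, n_ab_ctrl, n_ctrl, "controls"),
    )


def synergy_factor(
    t: TwoByTwoByTwoTable,
    z: float = 1.96,
    small_cell_threshold: int = 5,
) -> SynergyResult:
    """Synergy factor with log-normal CI.

    If the smallest of the eight cells is below ``small_cell_threshold``,
    0.5 is added to every cell (Haldane-Anscombe) before estimation and
    the correction flag is set. The variance of ln SF is the sum of
    reciprocals of the same (possibly corrected) working cells.
    """
    raw = list(t.case) + list(t.control)
    correction = min(raw) < small_cell_threshold
    cells = [x + 0.5 for x in raw] if correction else [float(x) for x in raw]
    if min(cells) <= 0:
        raise DegenerateTableError(
            "zero working cell; synergy factor undefined"
        )
    c11, c10, c01, c00, k11, k10, k01, k00 = cells
    or11 = (c11 / c00) / (k11 / k00)
    or10 = (c10 / c00) / (k10 / k00)
    or01 = (c01 / c00) / (k01 / k00)
    sf = or11 / (or10 * or01)
    se = math.sqrt(sum(1.0 / x for x in cells))
    ci_low = math.exp(math.log(sf) - z * se)
    ci_high = math.exp(math.log(sf) + z * se)
    return SynergyResult(sf, se, ci_low, ci_high, correction, or11, or10, or01)


def _solve_family(t: TwoByTwoByTwoTable):
    """Express the conditional table family in terms of the pivot cell.

    Holding all three two-way margins fixed, every cell is an affine
    function of the pivot p = case[1,1] with slope +-1 (e.g.
    case10 = caseA - p, ctrl11 = m11 - p where caseA is the status x A
    margin and m11 the A x B margin). Returns (offsets, signs) such that
    cell_k(p) = offsets[k] + signs[k] * p, plus the feasible pivot range
    where all eight cells are non-negative.
    """
    c11, c10, c01, c00 = t.case
    k11, k10, k01, k00 = t.control
    case_a = c11 + c10  # status x A margin, case row, A = 1
    case_b = c11 + c01
    n_case = sum(t.case)
    m11 = c11 + k11  # A x B margin cells (pooled over status)
    m10 = c10 + k10
    m01 = c01 + k01
    m00 = c00 + k00
    # cells as offset + sign * pivot
    offsets = np.array(
        [
            0,  # case 11
            case_a,  # case 10
            case_b,  # case 01
            n_case - case_a - case_b,  # case 00
            m11,  # ctrl 11
            m10 - case_a,  # ctrl 10
            m01 - case_b,  # ctrl 01
            m00 - n_case + case_a + case_b,  # ctrl 00
        ],
        dtype=np.int64,
    )
    signs = np.array([1, -1, -1, 1, -1, 1, 1, -1], dtype=np.int64)
    # feasible: offsets + signs * p >= 0 for all eight cells
    lo = 0
    hi = None
    for off, sg in zip(offsets, signs):
        if sg == 1:
            lo = max(lo, -off)
        else:
            hi = off if hi is None else min(hi, off)
    if hi is None or hi < lo:
        raise DegenerateTableError("infeasible margins for exact test")
    return offsets, signs, int(lo), int(hi)


def flint_exact(t: TwoByTwoByTwoTable) -> FlintResult:
    """Conditional exact test of no three-way interaction.

    All three two-way margins are held fixed; the null probability of each
    feasible table is proportional to 1 / prod(cell!), normalized over the
    pivot range. ``p_flint`` sums tables whose null probability is at most
    the observed (relative tie tolerance 1e-12); ``p_synergy`` is the
    one-sided tail with pivot >= observed (the synergistic direction).
    """
    offsets, signs, lo, hi = _solve_family(t)
    pivots = np.arange(lo, hi + 1, dtype=np.int64)
    cells = offsets[None, :] + signs[None, :] * pivots[:, None]  # (m, 8)
    log_weights = -gammaln(cells + 1.0).sum(axis=1)
    log_norm = logsumexp(log_weights)
    log_probs = log_weights - log_norm
    obs_idx = t.case[0] - lo
    log_obs = log_probs[obs_idx]
    # probability ordering with relative tie tolerance on the linear scale
    keep = log_probs <= log_obs + math.log1p(_TIE_RTOL)
    p_flint = float(np.exp(logsumexp(log_probs[keep])))
    p_synergy = float(np.exp(logsumexp(log_probs[obs_idx:])))
    return FlintResult(
        p_flint=min(1.0, p_flint),
        n_tables=len(pivots),
        free_range=(lo, hi),
        p_synergy=min(1.0, p_synergy),
    )


def classify_interaction(
    sf_res: SynergyResult,
    flint_res: FlintResult,
    alpha: float = 0.05,
) -> InteractionCall:
    """EPISTATIC iff the exact test rejects AND the SF CI excludes 1;
    SUGGESTIVE iff exactly one criterion holds; else NOT_SUPPORTED."""
    flint_ok = flint_res.p_flint < alpha
    sf_ok = sf_res.ci_excludes_one
    if flint_ok and sf_ok:
        return InteractionCall.EPISTATIC
    if flint_ok or sf_ok:
        return InteractionCall.SUGGESTIVE
    return InteractionCall.NOT_SUPPORTED


@dataclass(frozen=True)
class EpistasisResult:
    """Bundle of everything computed for one factor pair."""

    pair: str
    table: TwoByTwoByTwoTable
    synergy: SynergyResult
    flint: FlintResult
    classification: InteractionCall

    def to_row(self) -> dict:
        t = self.table
        s = self.synergy
        return {
            "pair": self.pair,
            "case_cells": ",".join(map(str, t.case)),
            "control_cells": ",".join(map(str, t.control)),
            "sf": s.sf,
            "sf_ci_low": s.ci_low,
            "sf_ci_high": s.ci_high,
            "correction_applied": s.correction_applied,
            "p_flint": self.flint.p_flint,
            "p_synergy": self.flint.p_synergy,
            "classification": self.classification.value,
        }


def analyze_pair(
    cohort: CohortTable,
    feat_a: Feature,
    feat_b: Feature,
    alpha: float = 0.05,
    small_cell_threshold: int = 5,
    z: float = 1.96,
    calls=None,
) -> EpistasisResult:
    """End-to-end epistasis assessment for one feature pair on a cohort."""
    t = build_2x2x2(cohort, feat_a, feat_b, calls)
    return analyze_table(
        t,
        pair=f"{feat_a.name} + {feat_b.name}",
        alpha=alpha,
        small_cell_threshold=small_cell_threshold,
        z=z,
    )


def analyze_table(
    t: TwoByTwoByTwoTable,
    pair: str = "",
    alpha: float = 0.05,
    small_cell_threshold: int = 5,
    z: float = 1.96,
) -> EpistasisResult:
    sf_res = synergy_factor(t, z=z, small_cell_threshold=small_cell_threshold)
    flint_res = flint_exact(t)
    call = classify_interaction(sf_res, flint_res, alpha=alpha)
    return EpistasisResult(pair, t, sf_res, flint_res, call)
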