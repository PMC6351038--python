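"""Mitochondrial haplogroup assignment from five diagnostic SNPs.

Four West-Eurasian haplogroups are distinguished by the extended haplotype
over rCRS positions (1719, 7028, 9055, 10398, 12308):

======  =====  =====  =====  ======  ======
label    1719   7028   9055   10398   12308
======  =====  =====  =====  ======  ======
H        G      C      G      A       A
J        G      T      G      G       A
K        G      T      A      G       G
U        G      T      G      A       G
======  =====  =====  =====  ======  ======

Any other complete five-tuple is classed OTHER; any missing marker yields
UNKNOWN. The decision table is exhaustive and exclusive over the 4^5
complete tuples (the four defining patterns are pairwise distinct).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import MISSING, CohortTable, MtMarkerSet, SubjectRecord
from .errors import DegenerateTableError

HAPLOGROUP_PATTERNS: dict[str, tuple[str, str, str, str, str]] = {
    "H": ("G", "C", "G", "A", "A"),
    "J": ("G", "T", "G", "G", "A"),
    "K": ("G", "T", "A", "G", "G"),
    "U": ("G", "T", "G", "A", "G"),
}

_PATTERN_TO_LABEL = {pat: lab for lab, pat in HAPLOGROUP_PATTERNS.items()}

LABELS = ("H", "J", "K", "U", "OTHER")  # reportable classes; UNKNOWN excluded


@dataclass(frozen=True)
class HaplogroupCall:
    label: str  # one of H, J, K, U, OTHER, UNKNOWN
    matched_pattern: tuple[str, ...] = ()

    @property
    def known(self) -> bool:
        return self.label != "UNKNOWN"


def call_haplogroup(mt: MtMarkerSet) -> HaplogroupCall:
    """Assign a haplogroup label to one marker set.

    UNKNOWN iff any marker is missing; H/J/K/U iff the complete five-tuple
    equals the corresponding defining pattern; OTHER for every other
    complete tuple.
    """
    alleles = mt.as_tuple()
    if MISSING in alleles:
        return HaplogroupCall("UNKNOWN")
    label = _PATTERN_TO_LABEL.get(alleles)
    if label is None:
        return HaplogroupCall("OTHER", alleles)
    return HaplogroupCall(label, alleles)


def call_cohort(cohort: CohortTable) -> dict[str, HaplogroupCall]:
    """Call every subject; keyed by subject_id."""
    return {s.subject_id: call_haplogroup(s.mt) for s in cohort}


def haplogroup_frequencies(
    cohort: CohortTable, sex: str | None = None
) -> pd.DataFrame:
    """Per-status haplogroup counts and percentages.

    Percentages are computed among subjects whose call is not UNKNOWN
    (complete-case), so each status column sums to 100 across
    H/J/K/U/OTHER. ``sex`` optionally restricts to one stratum ("F"/"M");
    subjects with missing sex belong to neither stratum.

    Returns a DataFrame indexed by label with columns
    ``n_case``, ``pct_case``, ``n_control``, ``pct_control``.
    """
    if sex is not None:
        cohort = cohort.subset(lambda s: s.sex == sex)
    calls = [
        (s.is_case, call_haplogroup(s.mt).label)
        for s in cohort
        if call_haplogroup(s.mt).known
    ]
    n_case = sum(1 for is_case, _ in calls if is_case)
    n_control = sum(1 for is_case, _ in calls if not is_case)
    if n_case == 0 and n_control == 0:
        raise DegenerateTableError(
            "empty stratum: no subjects with complete mtDNA genotypes"
            + (f" and sex {sex}" if sex is not None else "")
        )
    rows = []
    for label in LABELS:
        c = sum(1 for is_case, lab in calls if is_case and lab == label)
        k = sum(1 for is_case, lab in calls if not is_case and lab == label)
        rows.append(
            {
                "haplogroup": label,
                "n_case": c,
                "pct_case": 100.0 * c / n_case if n_case else float("nan"),
                "n_control": k,
                "pct_control": 100.0 * k / n_control
                if n_control
                else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("haplogroup")


def subject_haplogroup(subject: SubjectRecord) -> HaplogroupCall:
    return call_haplogroup(subject.mt)
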