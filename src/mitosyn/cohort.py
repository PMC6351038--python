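"""Cohort data model and tabular I/O.

A cohort is a case-control collection of subjects, each carrying haploid
genotypes at five diagnostic mtDNA positions (rCRS coordinates 1719, 7028,
9055, 10398 and 12308) plus unordered diploid genotypes at zero or more
rsID-named nuclear loci.

The on-disk format is a UTF-8 tab-separated table with mandatory columns
``subject_id``, ``status`` (``case``/``control``), ``sex`` (``F``/``M``/``.``)
and ``mt_1719`` .. ``mt_12308`` (single base or ``.``), followed by nuclear
columns named by rsID holding ``X/Y`` genotypes or ``.``. The missing token
is ``.`` throughout.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

from .errors import FormatError, IntegrityError, ParseError

MISSING = "."
NUCLEOTIDES = frozenset("ACGT")
MT_POSITIONS = (1719, 7028, 9055, 10398, 12308)
MT_COLUMNS = tuple(f"mt_{p}" for p in MT_POSITIONS)
MANDATORY_COLUMNS = ("subject_id", "status", "sex") + MT_COLUMNS


class Status(enum.Enum):
    CASE = "case"
    CONTROL = "control"


@dataclass(frozen=True)
class MtMarkerSet:
    """Haploid alleles at the five diagnostic mtDNA positions.

    Each field holds a single base (``A``/``C``/``G``/``T``) or ``.`` for
    missing. Heteroplasmy is not representable: one base per position.
    """

    allele_1719: str = MISSING
    allele_7028: str = MISSING
    allele_9055: str = MISSING
    allele_10398: str = MISSING
    allele_12308: str = MISSING

    def __post_init__(self) -> None:
        for pos, allele in zip(MT_POSITIONS, self.as_tuple()):
            if allele != MISSING and allele not in NUCLEOTIDES:
                raise ParseError(
                    f"invalid mtDNA allele {allele!r} at position {pos}"
                )

    def as_tuple(self) -> tuple[str, str, str, str, str]:
        return (
            self.allele_1719,
            self.allele_7028,
            self.allele_9055,
            self.allele_10398,
            self.allele_12308,
        )

    @property
    def complete(self) -> bool:
        return MISSING not in self.as_tuple()

    @classmethod
    def from_tuple(cls, alleles: Sequence[str]) -> "MtMarkerSet":
        if len(alleles) != 5:
            raise ParseError(f"expected 5 mtDNA alleles, got {len(alleles)}")
        return cls(*alleles)


@dataclass(frozen=True)
class NuclearGenotype:
    """Unordered diploid genotype at one nuclear locus.

    ``alleles`` is a sorted pair, so A/G and G/A compare equal; ``None``
    marks a missing genotype.
    """

    locus: str
    alleles: tuple[str, str] | None

    @classmethod
    def from_token(cls, locus: str, token: str) -> "NuclearGenotype":
        if token == MISSING or token == "":
            return cls(locus, None)
        parts = token.split("/")
        if len(parts) != 2 or not all(parts):
            raise ParseError(f"invalid genotype token {token!r} at {locus}")
        a, b = sorted(parts)
        return cls(locus, (a, b))

    def to_token(self) -> str:
        if self.alleles is None:
            return MISSING
        return "/".join(self.alleles)

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    def carries(self, allele: str) -> bool:
        """Dominant coding: true if at least one copy of ``allele``."""
        return self.alleles is not None and allele in self.alleles

    def matches(self, genotype: tuple[str, str]) -> bool:
        """Exact unordered genotype match."""
        return self.alleles == tuple(sorted(genotype))


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    status: Status
    sex: str | None  # "F", "M" or None
    mt: MtMarkerSet
    nuclear: Mapping[str, NuclearGenotype] = field(default_factory=dict)

    @property
    def is_case(self) -> bool:
        return self.status is Status.CASE


@dataclass
class CohortTable:
    """Ordered subject collection plus the registry of nuclear loci present."""

    subjects: list[SubjectRecord]
    locus_registry: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        registry = set(self.locus_registry)
        for s in self.subjects:
            if s.subject_id in seen:
                raise IntegrityError(f"duplicate subject_id {s.subject_id!r}")
            seen.add(s.subject_id)
            extra = set(s.nuclear) - registry
            if extra:
                raise IntegrityError(
                    f"subject {s.subject_id!r} has loci outside the registry: "
                    f"{sorted(extra)}"
                )

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def n_case(self) -> int:
        return sum(1 for s in self.subjects if s.is_case)

    @property
    def n_control(self) -> int:
        return len(self.subjects) - self.n_case

    def cases(self) -> Iterable[SubjectRecord]:
        return (s for s in self.subjects if s.is_case)

    def controls(self) -> Iterable[SubjectRecord]:
        return (s for s in self.subjects if not s.is_case)

    def subset(self, predicate) -> "CohortTable":
        return CohortTable(
            [s for s in self.subjects if predicate(s)], list(self.locus_registry)
        )


def _parse_allele(token: str, *, strict: bool, line: int, column: str) -> str:
    token = token.strip().upper()
    if token in ("", MISSING):
        return MISSING
    if token in NUCLEOTIDES:
        return token
    if strict:
        raise ParseError(
            f"unparseable allele {token!r} at line {line}, column {column}"
        )
    return MISSING


def _parse_genotype(
    locus: str, token: str, *, strict: bool, line: int
) -> NuclearGenotype:
    try:
        return NuclearGenotype.from_token(locus, token.strip())
    except ParseError:
        if strict:
            raise ParseError(
                f"unparseable genotype {token!r} at line {line}, column {locus}"
            ) from None
        return NuclearGenotype(locus, None)


def read_cohort(source: str | TextIO, strict: bool = False) -> CohortTable:
    """Read a genotype TSV into a :class:`CohortTable`.

    ``source`` is a path or an open text stream. With ``strict`` off,
    unparseable allele/genotype tokens become missing; with it on they raise
    :class:`~mitosyn.errors.ParseError` naming line and column.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"missing mandatory columns: {missing_cols}")
    nuclear_cols = [c for c in df.columns if c not in MANDATORY_COLUMNS]

    subjects: list[SubjectRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        status_token = rec["status"].strip().lower()
        try:
            status = Status(status_token)
        except ValueError:
            raise ParseError(
                f"invalid status {rec['status']!r} at line {idx}"
            ) from None
        sex_token = rec["sex"].strip().upper()
        if sex_token in ("", MISSING):
            sex: str | None = None
        elif sex_token in ("F", "M"):
            sex = sex_token
        elif strict:
            raise ParseError(f"invalid sex {rec['sex']!r} at line {idx}")
        else:
            sex = None
        mt = MtMarkerSet.from_tuple(
            [
                _parse_allele(rec[c], strict=strict, line=idx, column=c)
                for c in MT_COLUMNS
            ]
        )
        nuclear = {
            loc: _parse_genotype(loc, rec[loc], strict=strict, line=idx)
            for loc in nuclear_cols
        }
        subjects.append(
            SubjectRecord(rec["subject_id"].strip(), status, sex, mt, nuclear)
        )
    return CohortTable(subjects, nuclear_cols)


def write_cohort(cohort: CohortTable, sink: str | TextIO) -> None:
    """Write a cohort back to the genotype TSV dialect (inverse of read)."""
    columns = list(MANDATORY_COLUMNS) + list(cohort.locus_registry)
    rows = []
    for s in cohort:
        row = {
            "subject_id": s.subject_id,
            "status": s.status.value,
            "sex": s.sex if s.sex is not None else MISSING,
        }
        row.update(dict(zip(MT_COLUMNS, s.mt.as_tuple())))
        for loc in cohort.locus_registry:
            g = s.nuclear.get(loc)
            row[loc] = g.to_token() if g is not None else MISSING
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(sink, sep="\t", index=False)


def _render(value, precision: int) -> str:
    if isinstance(value, bool):
        return str(value).lower()
    if isinstance(value, float):
        return f"{value:.{precision}g}"
    return str(value)


def write_results(
    rows: Sequence[Mapping],
    sink: str | TextIO,
    precision: int = 4,
    columns: Sequence[str] | None = None,
) -> None:
    """Write result records as TSV with stable column order.

    Column order is taken from the first row (or ``columns`` when given,
    which also enables a header-only file for empty ``rows``); floats are
    rendered with ``precision`` significant digits (default 4).
    """
    own = isinstance(sink, str)
    stream: TextIO = open(sink, "w", encoding="utf-8") if own else sink
    try:
        if columns is None:
            if not rows:
                return
            columns = list(rows[0].keys())
        else:
            columns = list(columns)
        stream.write("\t".join(columns) + "\n")
        for row in rows:
            stream.write(
                "\t".join(_render(row[c], precision) for c in columns) + "\n"
            )
    finally:
        if own:
            stream.close()


def cohort_from_string(text: str, strict: bool = False) -> CohortTable:
    """Convenience wrapper: parse a cohort from an in-memory TSV string."""
    return read_cohort(io.StringIO(text), strict=strict)
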