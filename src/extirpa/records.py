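"""Ingest heterogeneous occurrence records into per-species period summaries.

Historical faunal audits pool records from published checklists, museum
databases and modern monitoring schemes.  The sources disagree in how they
report dates (some datasets only state a collecting interval, coded here as a
fixed mid-point year) and abundance (some old lists describe a species as
"abundant" or "frequent" instead of counting individuals; such records are
scored with a fixed number of individuals, 10 by default).  This module
applies those coding rules, validates each row, and reduces the record stream
to per-species sums for an *old* and a *recent* survey period plus the years
strictly in between.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "OccurrenceRecord",
    "PeriodScheme",
    "CodingRules",
    "SpeciesFlags",
    "SpeciesSummary",
    "ParseResult",
    "parse_records",
    "summarize_by_period",
    "summaries_to_frame",
]

#: Columns that must exist in any occurrence table (values may be blank
#: row-wise where a coding rule fills them in).
REQUIRED_COLUMNS = ("species_id", "dataset", "year", "count")
OPTIONAL_COLUMNS = ("abundance_text", "bin_id", "family", "subfamily")

MIN_YEAR = 1850


@dataclass(frozen=True)
class OccurrenceRecord:
    """One dated count of one species from one source dataset."""

    species_id: str
    dataset: str
    year: int
    count: int
    abundance_text: str | None = None
    bin_id: str | None = None
    family: str | None = None
    subfamily: str | None = None

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValueError("species_id must be non-empty")
        if self.count < 0:
            raise ValueError(f"count must be >= 0, got {self.count}")
        current = datetime.date.today().year
        if not (MIN_YEAR <= self.year <= current):
            raise ValueError(
                f"year {self.year} outside plausible range [{MIN_YEAR}, {current}]"
            )


@dataclass(frozen=True)
class PeriodScheme:
    """Two disjoint, inclusive year intervals: an old and a recent period."""

    old: tuple[int, int] = (1923, 1943)
    recent: tuple[int, int] = (1993, 2013)

    def __post_init__(self) -> None:
        o0, o1 = self.old
        r0, r1 = self.recent
        if o0 > o1 or r0 > r1:
            raise ValueError("period bounds must satisfy start <= end")
        if o1 >= r0:
            raise ValueError("old period must end before the recent period starts")

    def classify_year(self, year: int) -> str:
        """Return 'old', 'recent', 'between', or 'outside'."""
        if self.old[0] <= year <= self.old[1]:
            return "old"
        if self.recent[0] <= year <= self.recent[1]:
            return "recent"
        if self.old[1] < year < self.recent[0]:
            return "between"
        return "outside"


@dataclass(frozen=True)
class CodingRules:
    """Dataset-level substitutions applied while parsing.

    ``fixed_years`` maps a dataset label to the calendar year every record of
    that dataset is coded with (mid-point of the source's collecting
    interval).  ``abundance_text_value`` is the number of individuals scored
    for records flagged as "abundant"/"frequent" without an explicit count.
    """

    fixed_years: Mapping[str, int] = field(default_factory=dict)
    abundance_text_value: int = 10


@dataclass(frozen=True)
class SpeciesFlags:
    """Out-of-band per-species annotations needed for classification."""

    is_cryptic: bool = False
    described_after_1943: bool = False
    family: str | None = None
    subfamily: str | None = None
    bin_id: str | None = None


@dataclass
class SpeciesSummary:
    """Per-species period sums plus the flags classification needs."""

    species_id: str
    n_old: int = 0
    n_recent: int = 0
    n_between: int = 0
    n_total: int = 0
    per_year: dict[int, int] = field(default_factory=dict)
    is_cryptic: bool = False
    described_after_1943: bool = False
    family: str | None = None
    subfamily: str | None = None
    bin_id: str | None = None


@dataclass
class ParseResult:
    """Parsed records plus a rejection report (never silently dropped)."""

    records: list[OccurrenceRecord]
    rejected: pd.DataFrame  # original row values + a 'reason' column

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def write_rejections(self, path: str | Path) -> None:
        self.rejected.to_csv(path, index=False)


def _clean(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    return text or None


def parse_records(
    table: str | Path | pd.DataFrame,
    coding_rules: CodingRules | None = None,
) -> ParseResult:
    """Parse a delimited occurrence table into validated records.

    Parameters
    ----------
    table:
        Path to a CSV/TSV file with a header, or an equivalent DataFrame.
        Required columns: ``species_id``, ``dataset``, ``year``, ``count``.
        Optional: ``abundance_text``, ``bin_id``, ``family``, ``subfamily``.
    coding_rules:
        Dataset-level year substitutions and the "abundant"/"frequent" score.

    Raises
    ------
    ValueError
        If a required column is missing (malformed *rows* are instead
        collected into the rejection report).
    """
    rules = coding_rules or CodingRules()
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        sep = "\t" if str(table).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(table, sep=sep, dtype=object)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"required column {col!r} missing from occurrence table")

    records: list[OccurrenceRecord] = []
    rejected_rows: list[dict] = []
    current_year = datetime.date.today().year

    for row in df.itertuples(index=False):
        raw = row._asdict()
        species = _clean(raw.get("species_id"))
        dataset = _clean(raw.get("dataset")) or ""
        abundance_text = _clean(raw.get("abundance_text"))

        def reject(reason: str) -> None:
            rejected_rows.append({**raw, "reason": reason})

        if species is None:
            reject("empty species_id")
            continue

        # Year: explicit value, else dataset-level fixed-year substitution.
        year_raw = _clean(raw.get("year"))
        if dataset in rules.fixed_years:
            year = rules.fixed_years[dataset]
        elif year_raw is not None:
            try:
                year = int(float(year_raw))
            except ValueError:
                reject(f"unparseable year {year_raw!r}")
                continue
        else:
            reject("blank year and no fixed-year rule for dataset")
            continue
        if not (MIN_YEAR <= year <= current_year):
            reject(f"year {year} outside [{MIN_YEAR}, {current_year}]")
            continue

        # Count: "abundant"/"frequent" flags override with the coded score.
        if abundance_text is not None:
            count = rules.abundance_text_value
        else:
            count_raw = _clean(raw.get("count"))
            if count_raw is None:
                reject("blank count without abundance_text flag")
                continue
            try:
                count = int(float(count_raw))
            except ValueError:
                reject(f"unparseable count {count_raw!r}")
                continue
            if count < 0:
                reject(f"negative count {count}")
                continue

        records.append(
            OccurrenceRecord(
                species_id=species,
                dataset=dataset,
                year=year,
                count=count,
                abundance_text=abundance_text,
                bin_id=_clean(raw.get("bin_id")),
                family=_clean(raw.get("family")),
                subfamily=_clean(raw.get("subfamily")),
            )
        )

    rejected = pd.DataFrame(rejected_rows, columns=[*df.columns, "reason"])
    return ParseResult(records=records, rejected=rejected)


def summarize_by_period(
    records: Iterable[OccurrenceRecord],
    scheme: PeriodScheme | None = None,
    species_flags: Mapping[str, SpeciesFlags] | None = None,
) -> list[SpeciesSummary]:
    """Reduce records to one :class:`SpeciesSummary` per species.

    Species present in ``species_flags`` but absent from the records receive
    an all-zero summary: voucher-only species with no usable dated record
    still need to be carried through classification.
    """
    scheme = scheme or PeriodScheme()
    flags = dict(species_flags or {})
    summaries: dict[str, SpeciesSummary] = {}

    def get(species_id: str) -> SpeciesSummary:
        if species_id not in summaries:
            fl = flags.get(species_id, SpeciesFlags())
            summaries[species_id] = SpeciesSummary(
                species_id=species_id,
                is_cryptic=fl.is_cryptic,
                described_after_1943=fl.described_after_1943,
                family=fl.family,
                subfamily=fl.subfamily,
                bin_id=fl.bin_id,
            )
        return summaries[species_id]

    for rec in records:
        s = get(rec.species_id)
        s.per_year[rec.year] = s.per_year.get(rec.year, 0) + rec.count
        s.n_total += rec.count
        where = scheme.classify_year(rec.year)
        if where == "old":
            s.n_old += rec.count
        elif where == "recent":
            s.n_recent += rec.count
        elif where == "between":
            s.n_between += rec.count
        # Record-level metadata fills summary fields when flags lack them.
        if s.family is None and rec.family is not None:
            s.family = rec.family
        if s.subfamily is None and rec.subfamily is not None:
            s.subfamily = rec.subfamily
        if s.bin_id is None and rec.bin_id is not None:
            s.bin_id = rec.bin_id

    for species_id in flags:
        get(species_id)  # materialize zero-count summaries

    return sorted(summaries.values(), key=lambda s: s.species_id)


def summaries_to_frame(summaries: Sequence[SpeciesSummary]) -> pd.DataFrame:
    """Tabular view of summaries (one row per species)."""
    return pd.DataFrame(
        {
            "species_id": [s.species_id for s in summaries],
            "family": [s.family for s in summaries],
            "subfamily": [s.subfamily for s in summaries],
            "n_old": [s.n_old for s in summaries],
            "n_recent": [s.n_recent for s in summaries],
            "n_between": [s.n_between for s in summaries],
            "n_total": [s.n_total for s in summaries],
            "is_cryptic": [s.is_cryptic for s in summaries],
            "described_after_1943": [s.described_after_1943 for s in summaries],
            "bin_id": [s.bin_id for s in summaries],
        }
    )
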