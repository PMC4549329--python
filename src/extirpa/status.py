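"""Abundance-status classification and extinction-rate arithmetic.

Every species in a pooled historical dataset is placed into exactly one of
nine abundance-status categories defined from its summed individuals in the
old period, the recent period, and the years in between, plus two
annotations (cryptic species known only from a DNA barcode cluster, and
species formally described after the old period closed).  The category of
interest is "extinct": species frequent in the old period (>= ``min_abundant``
individuals) yet never found in the recent period despite much higher recent
effort.  That asymmetry of effort is what the Fisher exact validation
quantifies, and the category counts feed simple but load-bearing
extinction-rate arithmetic against an estimated resident-species pool.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .records import SpeciesSummary

__all__ = [
    "StatusCategory",
    "CategoryCensus",
    "FisherResult",
    "ExtinctionRate",
    "UnclassifiableSpeciesError",
    "assign_category",
    "census",
    "fisher_validate",
    "extinction_rate",
    "percentage",
    "round_half_away",
    "extinction_rate_report",
]


class StatusCategory(enum.IntEnum):
    """The nine abundance-status categories (fixed code<->label bijection)."""

    CRYPTIC = 1
    RECENTLY_DESCRIBED = 2
    UNCLEAR_THROUGHOUT = 3
    UNCLEAR_NOT_RECENT = 4
    UNCLEAR_NOT_OLD = 5
    BETWEEN_ONLY = 6
    COMMON = 7
    SETTLER = 8
    EXTINCT = 9

    @property
    def label(self) -> str:
        return _LABELS[self]


_LABELS = {
    StatusCategory.CRYPTIC: "cryptic",
    StatusCategory.RECENTLY_DESCRIBED: "recently_described",
    StatusCategory.UNCLEAR_THROUGHOUT: "unclear_throughout",
    StatusCategory.UNCLEAR_NOT_RECENT: "unclear_not_recent",
    StatusCategory.UNCLEAR_NOT_OLD: "unclear_not_old",
    StatusCategory.BETWEEN_ONLY: "between_only",
    StatusCategory.COMMON: "common",
    StatusCategory.SETTLER: "settler",
    StatusCategory.EXTINCT: "extinct",
}


class UnclassifiableSpeciesError(ValueError):
    """Raised for species with no data and no status flags."""

    def __init__(self, species_ids: Sequence[str]):
        self.species_ids = list(species_ids)
        super().__init__(
            "species with zero counts in all periods and no flags: "
            + ", ".join(self.species_ids)
        )


def assign_category(summary: SpeciesSummary, min_abundant: int = 10) -> StatusCategory:
    """Assign the single abundance-status category of a species.

    Precedence: the two annotation categories (cryptic, recently described)
    override the abundance rules; among the abundance rules the extinct,
    settler and common categories are checked before the unclear ones.
    """
    if summary.is_cryptic:
        return StatusCategory.CRYPTIC
    if summary.described_after_1943:
        return StatusCategory.RECENTLY_DESCRIBED

    n_old, n_recent, n_between = summary.n_old, summary.n_recent, summary.n_between
    if n_old >= min_abundant and n_recent == 0:
        return StatusCategory.EXTINCT
    if n_recent >= min_abundant and n_old == 0:
        return StatusCategory.SETTLER
    if n_old + n_recent >= min_abundant and n_old > 0 and n_recent > 0:
        return StatusCategory.COMMON
    if n_old > 0 and n_recent > 0:  # sum necessarily < min_abundant here
        return StatusCategory.UNCLEAR_THROUGHOUT
    if 0 < n_old < min_abundant and n_recent == 0:
        return StatusCategory.UNCLEAR_NOT_RECENT
    if n_old == 0 and 0 < n_recent < min_abundant:
        return StatusCategory.UNCLEAR_NOT_OLD
    if n_old == 0 and n_recent == 0 and n_between > 0:
        return StatusCategory.BETWEEN_ONLY
    raise UnclassifiableSpeciesError([summary.species_id])


@dataclass
class CategoryCensus:
    """Counts of species per category; a partition of the classified list."""

    counts: dict[int, int]
    total: int
    assignments: dict[str, StatusCategory] = field(default_factory=dict)

    def species_in(self, category: StatusCategory | int) -> list[str]:
        cat = StatusCategory(category)
        return sorted(s for s, c in self.assignments.items() if c == cat)


def census(
    summaries: Iterable[SpeciesSummary], min_abundant: int = 10
) -> CategoryCensus:
    """Classify every species; raise listing ids if any is unclassifiable."""
    counts = {int(c): 0 for c in StatusCategory}
    assignments: dict[str, StatusCategory] = {}
    bad: list[str] = []
    for s in summaries:
        try:
            cat = assign_category(s, min_abundant=min_abundant)
        except UnclassifiableSpeciesError:
            bad.append(s.species_id)
            continue
        counts[int(cat)] += 1
        assignments[s.species_id] = cat
    if bad:
        raise UnclassifiableSpeciesError(bad)
    return CategoryCensus(counts=counts, total=sum(counts.values()), assignments=assignments)


@dataclass(frozen=True)
class FisherResult:
    """Exact test of one species' period split against the total effort split."""

    table: tuple[tuple[int, int], tuple[int, int]]
    p_two_sided: float
    p_one_sided: float
    odds_ratio: float


def fisher_validate(
    n_old_sp: int, n_recent_sp: int, total_old: int, total_recent: int
) -> FisherResult:
    """Fisher exact test of a species' old/recent counts vs. overall effort.

    The 2x2 table is ``[[n_old_sp, n_recent_sp], [total_old - n_old_sp,
    total_recent - n_recent_sp]]``.  Two-sided p sums all tables with point
    probability <= the observed one; the one-sided p is taken in the
    direction of the observed deviation.
    """
    if n_old_sp > total_old or n_recent_sp > total_recent:
        raise ValueError("species counts cannot exceed period totals")
    if min(n_old_sp, n_recent_sp, total_old, total_recent) < 0:
        raise ValueError("all counts must be non-negative")
    if total_old + total_recent == 0:
        raise ValueError("zero grand total")
    table = [[n_old_sp, n_recent_sp], [total_old - n_old_sp, total_recent - n_recent_sp]]
    odds, p_two = stats.fisher_exact(table, alternative="two-sided")
    # One-sided in the direction the species deviates from overall effort.
    grand = total_old + total_recent
    expected_old = (n_old_sp + n_recent_sp) * total_old / grand
    direction = "greater" if n_old_sp >= expected_old else "less"
    _, p_one = stats.fisher_exact(table, alternative=direction)
    return FisherResult(
        table=((table[0][0], table[0][1]), (table[1][0], table[1][1])),
        p_two_sided=float(p_two),
        p_one_sided=float(p_one),
        odds_ratio=float(odds),
    )


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def percentage(part: float, whole: float) -> float:
    """Plain percentage 100*part/whole (no pool adjustment)."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return 100.0 * part / whole


@dataclass(frozen=True)
class ExtinctionRate:
    """Share of the resident pool lost: 100*n/(pool + n)."""

    n_extinct: int
    resident_pool: float
    percent: float
    rounded_percent: int


def extinction_rate(n_extinct: int, resident_pool: float) -> ExtinctionRate:
    """Extinct species as a share of the estimated pool plus the losses.

    The resident pool is estimated from recent data only, so the extinct
    species are added back to the denominator: percent =
    100*n_extinct/(resident_pool + n_extinct).
    """
    if n_extinct < 0:
        raise ValueError("n_extinct must be >= 0")
    if resident_pool <= 0:
        raise ValueError("resident_pool must be > 0")
    pct = 100.0 * n_extinct / (resident_pool + n_extinct)
    return ExtinctionRate(
        n_extinct=n_extinct,
        resident_pool=resident_pool,
        percent=pct,
        rounded_percent=round_half_away(pct),
    )


def extinction_rate_report(
    n_extinct: int,
    resident_pool: float,
    n_secure: int | None = None,
    n_unclear_not_recent: int = 0,
    n_total: int | None = None,
    n_common: int | None = None,
    n_settler: int | None = None,
) -> dict[str, int]:
    """Low / best / high extinction-rate bounds plus context shares.

    * ``best``: all extinct-category species against the pool.
    * ``low``: only the ``n_secure`` species whose identification is beyond
      doubt (defaults to ``n_extinct``).
    * ``high``: extinct plus all not-seen-recently unclear species, as a
      share of the pool augmented by the confirmed losses.
    * ``share_of_higher_abundance``: extinct among the common + settler +
      extinct species (those abundant in at least one period).
    * ``share_of_total``: extinct among every species ever recorded.
    """
    out: dict[str, int] = {}
    out["best_percent"] = extinction_rate(n_extinct, resident_pool).rounded_percent
    secure = n_extinct if n_secure is None else n_secure
    out["low_percent"] = extinction_rate(secure, resident_pool).rounded_percent
    out["high_percent"] = round_half_away(
        percentage(n_extinct + n_unclear_not_recent, resident_pool + n_extinct)
    )
    if n_common is not None and n_settler is not None:
        out["share_of_higher_abundance_percent"] = round_half_away(
            percentage(n_extinct, n_common + n_settler + n_extinct)
        )
    if n_total is not None:
        out["share_of_total_percent"] = round_half_away(percentage(n_extinct, n_total))
    return out
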