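"""Community demography: residency records, conception dates, philopatry,
and the actual/potential parent-pair table.

The operations here encode the observational side of an inbreeding-avoidance
study in a habituated primate community with overlapping generations,
female-biased (but incomplete) dispersal and immigration:

* conception dates are back-calculated from birth dates with a fixed
  gestation offset (228 days);
* an individual counts as "reproductively aged" from 10.5 years;
* immigrant females, whose true ages are unknown, are assumed to arrive at
  13 years (the typical female dispersal age);
* the female philopatry rate is the percentage of natal females who reached
  the dispersal age during a study window but never emigrated;
* for each offspring, the *actual* parent pair (mother, sire) is contrasted
  with *potential* pairs: the mother paired with every other genotyped,
  reproductively aged male co-resident with her within +/-15 days of the
  conception date.  The potential pairs define the random-mating null.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, NamedTuple, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

Date = dt.date

#: Gestation offset: conception is this many days before the birth date.
GESTATION_DAYS = 228
#: Minimum age (years) for an individual to count as reproductively aged.
REPRODUCTIVE_AGE_YEARS = 10.5
#: Typical age (years) at which females disperse to a new community.
DISPERSAL_AGE_YEARS = 13
#: Assumed age (years) of immigrant females on arrival.
IMMIGRANT_ARRIVAL_AGE_YEARS = 13
#: Mean calendar-year length used for fractional ages.
DAYS_PER_YEAR = 365.25

NATALITY_LEVELS = ("natal", "immigrant", "unknown")
PAIR_TABLE_COLUMNS = (
    "offspring_id",
    "mother_id",
    "male_id",
    "pair_kind",
    "natality",
    "relatedness",
)


class RecordError(ValueError):
    """Inconsistent or incomplete demographic records."""


class UndefinedRateError(ZeroDivisionError):
    """A rate whose denominator is empty (no eligible individuals)."""


class MissingRelatednessError(KeyError):
    """Relatedness estimates are unavailable for retained parent pairs."""

    def __init__(self, pairs: Sequence[tuple[str, str]]):
        self.pairs = list(pairs)
        super().__init__(
            "missing relatedness for %d pair(s): %s"
            % (len(self.pairs), ", ".join(f"({a},{b})" for a, b in self.pairs[:10]))
        )


def add_years(date: Date, years: int) -> Date:
    """Calendar-aware year addition (Feb 29 maps to Mar 1 off leap years)."""
    try:
        return date.replace(year=date.year + years)
    except ValueError:  # Feb 29 in a non-leap target year
        return date.replace(year=date.year + years, month=3, day=1)


def conception_date(birth_date: Date) -> Date:
    """Conception date: exactly ``GESTATION_DAYS`` before the birth date."""
    return birth_date - dt.timedelta(days=GESTATION_DAYS)


@dataclass
class IndividualRecord:
    """One community member: sex, dates, natality and residency intervals.

    ``residency`` is an ordered list of ``(start, end)`` intervals, closed on
    both ends; ``end=None`` means the individual is still resident at the end
    of the records.  Immigrant females with unknown birth dates have their
    birth date imputed as ``immigration_date`` minus 13 years.
    """

    id: str
    sex: str  # "female" | "male"
    birth_date: Date
    birth_date_known: bool = True
    death_date: Optional[Date] = None
    natality: str = "unknown"  # "natal" | "immigrant" | "unknown"
    immigration_date: Optional[Date] = None
    emigration_date: Optional[Date] = None
    residency: list[tuple[Date, Optional[Date]]] = field(default_factory=list)
    in_genetic_dataset: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise RecordError(f"{self.id}: invalid sex {self.sex!r}")
        if self.natality not in NATALITY_LEVELS:
            raise RecordError(f"{self.id}: invalid natality {self.natality!r}")
        if self.natality == "immigrant":
            if self.immigration_date is None:
                raise RecordError(f"{self.id}: immigrant without immigration_date")
            if not self.birth_date_known and self.birth_date is None:
                self.birth_date = add_years(
                    self.immigration_date, -IMMIGRANT_ARRIVAL_AGE_YEARS
                )
        if self.birth_date is None:
            raise RecordError(f"{self.id}: missing birth_date")
        if self.death_date is not None and self.death_date < self.birth_date:
            raise RecordError(f"{self.id}: death_date precedes birth_date")
        prev_end: Optional[Date] = None
        for k, (start, end) in enumerate(self.residency):
            if end is not None and end < start:
                raise RecordError(f"{self.id}: residency interval {k} ends before start")
            if k > 0:
                if prev_end is None:
                    raise RecordError(f"{self.id}: open residency interval not last")
                if start <= prev_end:
                    raise RecordError(f"{self.id}: residency intervals overlap/unordered")
            prev_end = end
        if (
            self.immigration_date is not None
            and self.residency
            and self.immigration_date not in [s for s, _ in self.residency]
        ):
            raise RecordError(
                f"{self.id}: immigration_date does not open a residency interval"
            )

    @classmethod
    def immigrant_female(
        cls, id: str, immigration_date: Date, **kwargs
    ) -> "IndividualRecord":
        """An immigrant female with birth date imputed as arrival - 13 years."""
        kwargs.setdefault("residency", [(immigration_date, None)])
        return cls(
            id=id,
            sex="female",
            birth_date=add_years(immigration_date, -IMMIGRANT_ARRIVAL_AGE_YEARS),
            birth_date_known=False,
            natality="immigrant",
            immigration_date=immigration_date,
            **kwargs,
        )

    def resident_days_in_window(self, start: Date, end: Date) -> int:
        """Number of residency days inside the closed window [start, end]."""
        days = 0
        for s, e in self.residency:
            lo = max(s, start)
            hi = min(e, end) if e is not None else end
            if hi >= lo:
                days += (hi - lo).days + 1
        return days

    @property
    def currently_resident(self) -> bool:
        return bool(self.residency) and self.residency[-1][1] is None


def age_at(individual: IndividualRecord, date: Date) -> float:
    """Fractional age in years (365.25-day years) at ``date``.

    Raises :class:`RecordError` if ``date`` precedes the birth date, which
    signals inconsistent records.
    """
    if date < individual.birth_date:
        raise RecordError(
            f"{individual.id}: date {date} precedes birth date {individual.birth_date}"
        )
    return (date - individual.birth_date).days / DAYS_PER_YEAR


def is_reproductively_aged(individual: IndividualRecord, date: Date) -> bool:
    """True iff the individual is at least 10.5 years old at ``date``.

    Individuals not yet born at ``date`` are simply not reproductively aged
    (no error), so the predicate can be applied to arbitrary rosters.
    """
    if date < individual.birth_date:
        return False
    return age_at(individual, date) >= REPRODUCTIVE_AGE_YEARS


class PhilopatryResult(NamedTuple):
    numerator: int
    denominator: int
    rate: float  # percent


def philopatry_rate(
    records: Iterable[IndividualRecord],
    study_start: Date,
    study_end: Date,
) -> PhilopatryResult:
    """Rate of female philopatry over a study window.

    Denominator: natal females who reached their 13th birthday within
    ``[study_start, study_end]`` (inclusive on both ends; a female who died
    before that birthday never reached the dispersal age and is excluded).
    Numerator: those who never emigrated — their residency runs open-ended
    through the end of the records, or closes only at death (emigration is
    a terminated residency with no death date).  The rate is a percentage.

    Raises :class:`UndefinedRateError` when no female is eligible.
    """
    num = den = 0
    for rec in records:
        if rec.sex != "female" or rec.natality != "natal":
            continue
        dispersal_birthday = add_years(rec.birth_date, DISPERSAL_AGE_YEARS)
        if not (study_start <= dispersal_birthday <= study_end):
            continue
        if rec.death_date is not None and rec.death_date < dispersal_birthday:
            continue
        den += 1
        if rec.emigration_date is None and (
            rec.currently_resident
            or (rec.residency and rec.residency[-1][1] == rec.death_date)
        ):
            num += 1
    if den == 0:
        raise UndefinedRateError(
            "philopatry rate undefined: no natal female reached dispersal age "
            "within the study window"
        )
    return PhilopatryResult(num, den, 100.0 * num / den)


@dataclass
class ParentageRecord:
    """Offspring with its known mother and (possibly unknown) sire."""

    offspring_id: str
    mother_id: str
    sire_id: Optional[str]
    birth_date: Date

    @property
    def conception_date(self) -> Date:
        return conception_date(self.birth_date)


def potential_sires(
    mother_id: str,
    conception: Date,
    actual_sire: Optional[str],
    records: Sequence[IndividualRecord],
    window_days: int = 15,
) -> set[str]:
    """Males defining the random-mating null for one conception.

    Returns genotyped males, reproductively aged at conception, with at least
    one day of community residency inside the closed window
    ``[conception - window_days, conception + window_days]``, excluding the
    actual sire.  Raises :class:`RecordError` if the mother herself was not
    resident in the window (inconsistent parentage record).
    """
    by_id = {r.id: r for r in records}
    if mother_id not in by_id:
        raise RecordError(f"unknown mother {mother_id}")
    lo = conception - dt.timedelta(days=window_days)
    hi = conception + dt.timedelta(days=window_days)
    mother = by_id[mother_id]
    if mother.resident_days_in_window(lo, hi) < 1:
        raise RecordError(
            f"mother {mother_id} not resident within +/-{window_days} days of "
            f"conception {conception}"
        )
    out: set[str] = set()
    for rec in records:
        if rec.sex != "male" or rec.id == actual_sire or not rec.in_genetic_dataset:
            continue
        if rec.resident_days_in_window(lo, hi) < 1:
            continue
        if not is_reproductively_aged(rec, conception):
            continue
        out.add(rec.id)
    return out


def enumerate_parent_pairs(
    parentage: Iterable[ParentageRecord],
    records: Sequence[IndividualRecord],
    window_days: int = 15,
) -> pd.DataFrame:
    """Actual and potential parent-pair rows, without relatedness.

    Offspring whose sire is unknown, or whose mother or sire is not in the
    genetic dataset, contribute no rows at all (neither actual nor potential),
    keeping actual/potential balanced per offspring.
    """
    by_id = {r.id: r for r in records}
    rows: list[dict] = []
    for rec in parentage:
        mother = by_id.get(rec.mother_id)
        sire = by_id.get(rec.sire_id) if rec.sire_id is not None else None
        if mother is None:
            raise RecordError(f"offspring {rec.offspring_id}: unknown mother {rec.mother_id}")
        if mother.sex != "female":
            raise RecordError(f"offspring {rec.offspring_id}: mother {rec.mother_id} is not female")
        if sire is not None and sire.sex != "male":
            raise RecordError(f"offspring {rec.offspring_id}: sire {rec.sire_id} is not male")
        if sire is None or not sire.in_genetic_dataset or not mother.in_genetic_dataset:
            continue
        conc = rec.conception_date
        pot = potential_sires(rec.mother_id, conc, rec.sire_id, records, window_days)
        if not pot:
            logger.warning(
                "offspring %s: no potential sires in the +/-%d-day window",
                rec.offspring_id,
                window_days,
            )
        rows.append(
            dict(
                offspring_id=rec.offspring_id,
                mother_id=rec.mother_id,
                male_id=rec.sire_id,
                pair_kind="actual",
                natality=mother.natality,
            )
        )
        for m in sorted(pot):
            rows.append(
                dict(
                    offspring_id=rec.offspring_id,
                    mother_id=rec.mother_id,
                    male_id=m,
                    pair_kind="potential",
                    natality=mother.natality,
                )
            )
    df = pd.DataFrame(rows, columns=[c for c in PAIR_TABLE_COLUMNS if c != "relatedness"])
    return df


def build_pair_table(
    parentage: Iterable[ParentageRecord],
    records: Sequence[IndividualRecord],
    relatedness_lookup: Callable[[str, str], float],
    window_days: int = 15,
) -> pd.DataFrame:
    """The pair table consumed by the dyadic beta GLMM.

    One *actual* row per offspring with a genotyped known mother and sire,
    plus one *potential* row per potential sire; the natality column is
    copied from the mother's record.  ``relatedness_lookup`` must cover every
    retained (mother, male) pair; otherwise a
    :class:`MissingRelatednessError` lists the offending pairs.
    """
    df = enumerate_parent_pairs(parentage, records, window_days)
    rel: list[float] = []
    missing: list[tuple[str, str]] = []
    for a, b in zip(df["mother_id"], df["male_id"]):
        try:
            rel.append(float(relatedness_lookup(a, b)))
        except KeyError:
            missing.append((a, b))
            rel.append(float("nan"))
    if missing:
        raise MissingRelatednessError(sorted(set(missing)))
    df = df.copy()
    df["relatedness"] = rel
    return df[list(PAIR_TABLE_COLUMNS)]
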