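"""Cumulative unique-patient cohorts per ingestion date and JSD comparison series.

At each ingestion date three labelled comparisons are computed:

1. all unique patients in the cohort vs. the census snapshot,
2. unique COVID-19 positive patients vs. the cumulative surveillance
   counts at that date, and
3. the cumulative surveillance counts vs. the census snapshot (a
   reference level against which the cohort comparisons can be read).

The signed difference ``delta = jsd_all_vs_census - jsd_pos_vs_surveillance``
summarizes which cohort comparison is the more representative: negative
means the all-patients-vs-census comparison is more representative,
positive means the positives-vs-surveillance comparison is.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass
from typing import IO, Sequence

import pandas as pd

from .cohort import (
    PatientRecord,
    ReferenceTable,
    ValidationError,
)
from .divergence import SupportPolicy, js_divergence
from .harmonize import HarmonizationPolicy, positive_records, tabulate

logger = logging.getLogger(__name__)

_DELTA_TOL = 1e-12

DELTA_NEGATIVE_LABEL = "all-patients comparison more representative"
DELTA_POSITIVE_LABEL = "positives-vs-surveillance comparison more representative"
DELTA_ZERO_LABEL = "equally representative"


@dataclass(frozen=True)
class CohortTimeline:
    """Cumulative unique-patient cohorts at each ingestion date.

    ``cohorts[i]`` holds every unique patient with batch_date ≤
    ``dates[i]``; ``positives[i]`` is its COVID-19 positive subset.
    Cohorts are nested by construction.
    """

    dates: tuple[_dt.date, ...]
    cohorts: tuple[tuple[PatientRecord, ...], ...]
    positives: tuple[tuple[PatientRecord, ...], ...]

    def __post_init__(self) -> None:
        sizes = [len(c) for c in self.cohorts]
        if any(b < a for a, b in zip(sizes, sizes[1:])):
            raise ValidationError("cohort sizes must be non-decreasing over dates")


@dataclass(frozen=True)
class ComparisonSeries:
    """Per-date JSD values for the three labelled comparisons plus delta."""

    category: str
    dates: tuple[_dt.date, ...]
    jsd_all_vs_census: tuple[float, ...]
    jsd_pos_vs_surveillance: tuple[float, ...]
    jsd_surveillance_vs_census: tuple[float, ...]
    delta: tuple[float, ...]
    n_all: tuple[int, ...]
    n_pos: tuple[int, ...]

    def __post_init__(self) -> None:
        for a, p, d in zip(
            self.jsd_all_vs_census, self.jsd_pos_vs_surveillance, self.delta
        ):
            if math.isnan(d):
                continue
            if abs(d - (a - p)) > _DELTA_TOL:
                raise ValidationError("delta series inconsistent with its components")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": [d.isoformat() for d in self.dates],
                "jsd_all_vs_census": self.jsd_all_vs_census,
                "jsd_pos_vs_surveillance": self.jsd_pos_vs_surveillance,
                "jsd_surveillance_vs_census": self.jsd_surveillance_vs_census,
                "delta": self.delta,
                "n_all": self.n_all,
                "n_pos": self.n_pos,
            }
        )

    def to_tsv(self, sink: str | IO[str]) -> None:
        self.to_frame().to_csv(sink, sep="\t", index=False)


def deduplicate_to_index(records: Sequence[PatientRecord]) -> list[PatientRecord]:
    """Collapse to one record per patient: the index event (earliest batch date).

    A patient appearing on several ingestion dates keeps the demographics
    and COVID-19 status of the earliest one; ties on the same date keep
    the first occurrence in input order.  The number of collapsed
    duplicates is logged.
    """
    best: dict[str, PatientRecord] = {}
    collapsed = 0
    for record in records:
        held = best.get(record.patient_id)
        if held is None:
            best[record.patient_id] = record
        else:
            collapsed += 1
            if record.batch_date < held.batch_date:
                best[record.patient_id] = record
    if collapsed:
        logger.info("collapsed %d duplicate patient event(s) to index events", collapsed)
    return list(best.values())


def build_timeline(
    records: Sequence[PatientRecord], dates: Sequence[_dt.date]
) -> CohortTimeline:
    """Cumulative cohort at each date: all unique patients with batch_date ≤ d."""
    dates = tuple(dates)
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValidationError("timeline dates must be strictly increasing")
    ordered = sorted(records, key=lambda r: r.batch_date)
    cohorts = []
    positives = []
    for date in dates:
        cohort = tuple(r for r in ordered if r.batch_date <= date)
        cohorts.append(cohort)
        positives.append(tuple(positive_records(cohort)))
    return CohortTimeline(dates=dates, cohorts=tuple(cohorts), positives=tuple(positives))


def jsd_delta(jsd_all_vs_census: float, jsd_pos_vs_surveillance: float) -> float:
    """Signed JSD difference between the two cohort comparisons.

    Positive: the positives-vs-surveillance comparison is more
    representative; negative: the all-patients-vs-census comparison is.
    """
    return jsd_all_vs_census - jsd_pos_vs_surveillance


def interpret_delta(delta: float) -> str:
    """Human-readable reading of the delta sign convention."""
    if math.isnan(delta):
        return "undefined (no positive patients at this date)"
    if delta < 0:
        return DELTA_NEGATIVE_LABEL
    if delta > 0:
        return DELTA_POSITIVE_LABEL
    return DELTA_ZERO_LABEL


def comparison_series(
    timeline: CohortTimeline,
    census: ReferenceTable,
    surveillance: ReferenceTable,
    category: str,
    harmonization: HarmonizationPolicy | None = None,
    support_policy: SupportPolicy = SupportPolicy(),
    log_base: float = 2,
) -> ComparisonSeries:
    """The three per-date JSD comparison series for one demographic category.

    The census snapshot is time-invariant; the surveillance distribution
    at each ingestion date is the nearest series entry at or before that
    date (both series are cumulative, so the preceding cumulative total is
    the correct comparator when release dates do not line up; a gap is
    logged).  Dates with no positive patients yield NaN for the positive
    comparison and delta.
    """
    if census.kind != "snapshot":
        raise ValidationError("census reference must be a snapshot")
    if surveillance.kind != "cumulative_series":
        raise ValidationError("surveillance reference must be a cumulative series")
    harmonization = harmonization or HarmonizationPolicy()
    census_dist = census.at(timeline.dates[0]) if timeline.dates else None

    jsd_all, jsd_pos, jsd_ref, delta, n_all, n_pos = [], [], [], [], [], []
    for date, cohort, positives in zip(
        timeline.dates, timeline.cohorts, timeline.positives
    ):
        surv_dist = surveillance.at(date)
        all_dist = tabulate(cohort, category, harmonization) if cohort else None
        if all_dist is None:
            raise ValidationError(f"empty cohort at date {date}")
        a = js_divergence(all_dist, census_dist, log_base, support_policy).jsd
        r = js_divergence(surv_dist, census_dist, log_base, support_policy).jsd
        if positives:
            pos_dist = tabulate(positives, category, harmonization)
            p = js_divergence(pos_dist, surv_dist, log_base, support_policy).jsd
        else:
            logger.warning("no COVID-19 positive patients at %s; delta undefined", date)
            p = float("nan")
        jsd_all.append(a)
        jsd_pos.append(p)
        jsd_ref.append(r)
        delta.append(jsd_delta(a, p))
        n_all.append(len(cohort))
        n_pos.append(len(positives))
    return ComparisonSeries(
        category=category,
        dates=timeline.dates,
        jsd_all_vs_census=tuple(jsd_all),
        jsd_pos_vs_surveillance=tuple(jsd_pos),
        jsd_surveillance_vs_census=tuple(jsd_ref),
        delta=tuple(delta),
        n_all=tuple(n_all),
        n_pos=tuple(n_pos),
    )
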