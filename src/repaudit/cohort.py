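"""Domain types and delimited-text I/O for patient and reference tables.

The file dialect is fixed: UTF-8, comma-separated, mandatory header row,
dates in ISO-8601 (``YYYY-MM-DD``).  Raw demographic strings are never
interpreted here — vocabulary mapping is the :mod:`repaudit.harmonize`
module's single point of truth.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical ternary COVID-19 status values.
COVID_POSITIVE = "positive"
COVID_NEGATIVE = "negative"
COVID_UNKNOWN = "unknown"

_COVID_ALIASES = {
    "positive": COVID_POSITIVE,
    "pos": COVID_POSITIVE,
    "yes": COVID_POSITIVE,
    "true": COVID_POSITIVE,
    "1": COVID_POSITIVE,
    "negative": COVID_NEGATIVE,
    "neg": COVID_NEGATIVE,
    "no": COVID_NEGATIVE,
    "false": COVID_NEGATIVE,
    "0": COVID_NEGATIVE,
}


class SchemaError(ValueError):
    """A required column or label is missing or unresolvable."""


class ValidationError(ValueError):
    """Input violates a structural invariant (e.g. decreasing cumulative count)."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but carries no usable information."""


@dataclass(frozen=True)
class PatientRecord:
    """One de-identified patient at the index event.

    The demographics are the raw contributor strings; ``covid_status`` is
    the canonical ternary; ``batch_date`` is the ingestion date of the
    record.
    """

    patient_id: str
    age_at_index: int | None
    sex: str
    race: str
    ethnicity: str
    covid_status: str
    batch_date: _dt.date
    site_id: str | None = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValidationError("patient_id must be non-empty")
        if self.age_at_index is not None and not (0 <= self.age_at_index <= 120):
            raise ValidationError(
                f"age_at_index {self.age_at_index!r} outside [0, 120] "
                f"for patient {self.patient_id!r}"
            )
        if self.covid_status not in (COVID_POSITIVE, COVID_NEGATIVE, COVID_UNKNOWN):
            raise ValidationError(
                f"covid_status must be positive/negative/unknown, got {self.covid_status!r}"
            )
        if not isinstance(self.batch_date, _dt.date):
            raise ValidationError("batch_date must be a datetime.date")


@dataclass(frozen=True)
class DemographicSchema:
    """Canonical bin structure for one demographic category.

    ``category_name`` is one of ``age_at_index``, ``sex``, ``race``,
    ``ethnicity`` or ``race_ethnicity``.  ``age_bin_edges`` is used only
    for the age category.
    """

    category_name: str
    bin_labels: tuple[str, ...]
    age_bin_edges: tuple[int, ...] = ()
    not_reported_label: str = "Not Reported"

    def __post_init__(self) -> None:
        if len(set(self.bin_labels)) != len(self.bin_labels):
            raise ValidationError(f"bin_labels for {self.category_name!r} not unique")
        if self.age_bin_edges and any(
            b <= a for a, b in zip(self.age_bin_edges, self.age_bin_edges[1:])
        ):
            raise ValidationError("age_bin_edges must be strictly increasing")


@dataclass(frozen=True)
class CategoricalDistribution:
    """Ordered category labels with counts and derived probability masses.

    Counts are non-negative reals (reference tables may carry pre-scaled
    values); masses are always ``counts / counts.sum()``.
    """

    labels: tuple[str, ...]
    counts: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.counts):
            raise ValidationError("labels and counts length mismatch")
        if not self.labels:
            raise DegenerateInputError("distribution needs at least one label")
        if any(c < 0 for c in self.counts):
            raise ValidationError("counts must be non-negative")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("labels must be unique")

    @property
    def total(self) -> float:
        return float(sum(self.counts))

    @property
    def masses(self) -> np.ndarray:
        total = self.total
        if total == 0:
            raise DegenerateInputError("all-zero counts have no probability masses")
        return np.asarray(self.counts, dtype=float) / total

    def mass_of(self, label: str) -> float:
        return float(self.masses[self.labels.index(label)])

    def reindexed(self, labels: Sequence[str]) -> "CategoricalDistribution":
        """Return the same distribution over ``labels`` order (0 for absent)."""
        lookup = dict(zip(self.labels, self.counts))
        unknown = set(self.labels) - set(labels)
        if unknown:
            raise SchemaError(f"labels not present in target order: {sorted(unknown)}")
        return CategoricalDistribution(
            tuple(labels), tuple(float(lookup.get(lab, 0.0)) for lab in labels)
        )


@dataclass(frozen=True)
class ReferenceTable:
    """A reference population: a static snapshot or a dated cumulative series."""

    kind: str  # "snapshot" | "cumulative_series"
    schema: DemographicSchema
    snapshot: CategoricalDistribution | None = None
    series: tuple[tuple[_dt.date, CategoricalDistribution], ...] = field(
        default_factory=tuple
    )

    def __post_init__(self) -> None:
        if self.kind == "snapshot":
            if self.snapshot is None:
                raise ValidationError("snapshot ReferenceTable requires a distribution")
        elif self.kind == "cumulative_series":
            if not self.series:
                raise ValidationError("cumulative_series ReferenceTable requires entries")
            dates = [d for d, _ in self.series]
            if any(b <= a for a, b in zip(dates, dates[1:])):
                raise ValidationError("series dates must be strictly increasing")
            _check_monotone_series(self.series)
        else:
            raise ValidationError(f"unknown ReferenceTable kind {self.kind!r}")

    @property
    def dates(self) -> tuple[_dt.date, ...]:
        return tuple(d for d, _ in self.series)

    def at(self, date: _dt.date) -> CategoricalDistribution:
        """Distribution at ``date``: the snapshot, or the nearest series entry ≤ date."""
        if self.kind == "snapshot":
            assert self.snapshot is not None
            return self.snapshot
        best = None
        for d, dist in self.series:
            if d <= date:
                best = (d, dist)
            else:
                break
        if best is None:
            raise ValidationError(
                f"date {date} precedes first series date {self.series[0][0]}"
            )
        if best[0] != date:
            logger.debug("series lookup for %s used nearest preceding date %s", date, best[0])
        return best[1]


def _check_monotone_series(
    series: Sequence[tuple[_dt.date, CategoricalDistribution]]
) -> None:
    for (d_prev, dist_prev), (d_next, dist_next) in zip(series, series[1:]):
        prev = dict(zip(dist_prev.labels, dist_prev.counts))
        for label, count in zip(dist_next.labels, dist_next.counts):
            if count < prev.get(label, 0.0) - 1e-9:
                raise ValidationError(
                    f"cumulative count decreases for label {label!r} "
                    f"between {d_prev} and {d_next} ({prev.get(label, 0.0)} -> {count})"
                )


def parse_iso_date(value: str) -> _dt.date:
    """Strict ISO-8601 (YYYY-MM-DD) date parsing; anything else is an error."""
    return _dt.date.fromisoformat(str(value).strip())


DEFAULT_COLUMNS = (
    "patient_id",
    "age_at_index",
    "sex",
    "race",
    "ethnicity",
    "covid_status",
    "batch_date",
    "site_id",
)


def _parse_covid_status(raw: object) -> str:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return COVID_UNKNOWN
    text = str(raw).strip().lower()
    if not text:
        return COVID_UNKNOWN
    return _COVID_ALIASES.get(text, COVID_UNKNOWN)


def _parse_age(raw: object) -> int | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip()
    if not text:
        return None
    return int(float(text))


def read_patient_table(
    source: str | IO[str],
    column_map: Mapping[str, str] | None = None,
) -> list[PatientRecord]:
    """Read a patient metadata CSV into a list of :class:`PatientRecord`.

    ``column_map`` maps canonical field names (``patient_id`` ...) to the
    column names actually present in the file; omitted fields default to
    the canonical names.  Raw demographic strings are preserved verbatim.
    Rows whose ``batch_date`` does not parse as ISO-8601 are rejected and
    reported (with their 0-based row index) in a warning; all other rows
    are returned.  An empty file yields an empty list.
    """
    colmap = dict(zip(DEFAULT_COLUMNS, DEFAULT_COLUMNS))
    if column_map:
        colmap.update(column_map)
    try:
        frame = pd.read_csv(source, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    required = [c for c in DEFAULT_COLUMNS if c != "site_id"]
    for canonical in required:
        if colmap[canonical] not in frame.columns:
            raise SchemaError(
                f"required column {colmap[canonical]!r} (for field {canonical!r}) "
                f"not found; available: {list(frame.columns)}"
            )
    has_site = colmap["site_id"] in frame.columns

    records: list[PatientRecord] = []
    rejected: list[int] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        row_d = dict(zip(frame.columns, row))
        try:
            batch_date = parse_iso_date(row_d[colmap["batch_date"]])
        except ValueError:
            rejected.append(idx)
            continue
        records.append(
            PatientRecord(
                patient_id=str(row_d[colmap["patient_id"]]),
                age_at_index=_parse_age(row_d[colmap["age_at_index"]]),
                sex=str(row_d[colmap["sex"]]),
                race=str(row_d[colmap["race"]]),
                ethnicity=str(row_d[colmap["ethnicity"]]),
                covid_status=_parse_covid_status(row_d[colmap["covid_status"]]),
                batch_date=batch_date,
                site_id=str(row_d[colmap["site_id"]]) if has_site else None,
            )
        )
    if rejected:
        logger.warning(
            "rejected %d row(s) with unparseable batch_date at indices %s",
            len(rejected),
            rejected,
        )
    return records


def _canonicalize_label(raw: str, schema: DemographicSchema) -> str:
    fold = {lab.strip().casefold(): lab for lab in schema.bin_labels}
    key = str(raw).strip().casefold()
    if key not in fold:
        raise SchemaError(
            f"unknown label {raw!r} for category {schema.category_name!r}; "
            f"expected one of {list(schema.bin_labels)}"
        )
    return fold[key]


def read_reference_counts(
    source: str | IO[str],
    kind: str,
    schema: DemographicSchema,
) -> ReferenceTable:
    """Read a reference population CSV into a :class:`ReferenceTable`.

    Snapshot files have columns ``label,count``; cumulative series files
    have ``date,label,cumulative_count``.  Labels are canonicalized
    case-insensitively against ``schema.bin_labels``; unknown labels are
    errors, and any per-label decrease in a cumulative series is a
    validation error naming the date and label.
    """
    frame = pd.read_csv(source, dtype=str, keep_default_na=False)
    if kind == "snapshot":
        for col in ("label", "count"):
            if col not in frame.columns:
                raise SchemaError(f"snapshot reference missing column {col!r}")
        counts = {lab: 0.0 for lab in schema.bin_labels}
        for _, row in frame.iterrows():
            label = _canonicalize_label(row["label"], schema)
            counts[label] += float(row["count"])
        dist = CategoricalDistribution(
            tuple(schema.bin_labels), tuple(counts[lab] for lab in schema.bin_labels)
        )
        return ReferenceTable(kind="snapshot", schema=schema, snapshot=dist)
    if kind == "cumulative_series":
        for col in ("date", "label", "cumulative_count"):
            if col not in frame.columns:
                raise SchemaError(f"series reference missing column {col!r}")
        by_date: dict[_dt.date, dict[str, float]] = {}
        for _, row in frame.iterrows():
            date = parse_iso_date(row["date"])
            label = _canonicalize_label(row["label"], schema)
            by_date.setdefault(date, {lab: 0.0 for lab in schema.bin_labels})
            by_date[date][label] = float(row["cumulative_count"])
        series = tuple(
            (
                date,
                CategoricalDistribution(
                    tuple(schema.bin_labels),
                    tuple(by_date[date][lab] for lab in schema.bin_labels),
                ),
            )
            for date in sorted(by_date)
        )
        return ReferenceTable(kind="cumulative_series", schema=schema, series=series)
    raise ValidationError(f"unknown reference kind {kind!r}")


def counts_to_distribution(
    labels: Sequence[str], counts: Iterable[float]
) -> CategoricalDistribution:
    """Build a distribution whose masses are the count fractions per bin."""
    counts = tuple(float(c) for c in counts)
    dist = CategoricalDistribution(tuple(labels), counts)
    if dist.total == 0:
        raise DegenerateInputError("all counts are zero; no distribution defined")
    return dist


def write_distribution(dist: CategoricalDistribution, sink: str | IO[str]) -> None:
    """Write ``label,count`` rows; round-trips bit-identically through the read path."""
    frame = pd.DataFrame({"label": dist.labels, "count": dist.counts})
    frame.to_csv(sink, index=False)


def write_patient_table(records: Sequence[PatientRecord], sink: str | IO[str]) -> None:
    """Write patient records in the canonical patient-table dialect."""
    frame = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "age_at_index": ["" if r.age_at_index is None else r.age_at_index for r in records],
            "sex": [r.sex for r in records],
            "race": [r.race for r in records],
            "ethnicity": [r.ethnicity for r in records],
            "covid_status": [r.covid_status for r in records],
            "batch_date": [r.batch_date.isoformat() for r in records],
            "site_id": ["" if r.site_id is None else r.site_id for r in records],
        }
    )
    frame.to_csv(sink, index=False)


def write_reference_table(table: ReferenceTable, sink: str | IO[str]) -> None:
    """Write a reference table in the dialect :func:`read_reference_counts` expects."""
    if table.kind == "snapshot":
        assert table.snapshot is not None
        write_distribution(table.snapshot, sink)
        return
    rows = []
    for date, dist in table.series:
        for label, count in zip(dist.labels, dist.counts):
            rows.append({"date": date.isoformat(), "label": label, "cumulative_count": count})
    pd.DataFrame(rows, columns=["date", "label", "cumulative_count"]).to_csv(sink, index=False)
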