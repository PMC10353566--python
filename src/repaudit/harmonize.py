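"""Harmonization of raw demographic values into canonical bins.

Covers age binning (half-open 10-year bins by default, per the CDC
case-surveillance convention), case-insensitive vocabulary mapping for
sex/race/ethnicity, missing-value policy, and the OMB-style combined
race/ethnicity category that classifies patients as Hispanic or, if
non-Hispanic, by their race.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import yaml

from .cohort import (
    COVID_POSITIVE,
    CategoricalDistribution,
    DegenerateInputError,
    DemographicSchema,
    PatientRecord,
    counts_to_distribution,
)

logger = logging.getLogger(__name__)

NOT_REPORTED = "Not Reported"
HISPANIC = "Hispanic"
NON_HISPANIC = "Non-Hispanic"

RETAIN_AS_BIN = "retain_as_bin"
DROP = "drop"
IMPUTE_NON_HISPANIC = "impute_non_hispanic"

DEFAULT_AGE_EDGES = (0, 10, 20, 30, 40, 50, 60, 70, 80)

DEFAULT_SEX_LABELS = ("Male", "Female", "Other")
DEFAULT_ETHNICITY_LABELS = (HISPANIC, NON_HISPANIC)
DEFAULT_RACE_LABELS = (
    "White",
    "Black",
    "Asian",
    "American Indian or Alaska Native",
    "Native Hawaiian or Other Pacific Islander",
    "Other",
)

CATEGORIES = ("age_at_index", "sex", "race", "ethnicity", "race_ethnicity")


def _identity_vocab(labels: Sequence[str]) -> dict[str, str]:
    return {lab.casefold(): lab for lab in labels}


def _default_sex_vocab() -> dict[str, str]:
    vocab = _identity_vocab(DEFAULT_SEX_LABELS)
    vocab.update({"m": "Male", "f": "Female"})
    return vocab


def _default_race_vocab() -> dict[str, str]:
    vocab = _identity_vocab(DEFAULT_RACE_LABELS)
    vocab.update(
        {
            "black or african american": "Black",
            "african american": "Black",
        }
    )
    return vocab


def _default_ethnicity_vocab() -> dict[str, str]:
    vocab = _identity_vocab(DEFAULT_ETHNICITY_LABELS)
    vocab.update(
        {
            "hispanic or latino": HISPANIC,
            "not hispanic or latino": NON_HISPANIC,
            "non-hispanic or latino": NON_HISPANIC,
        }
    )
    return vocab


def age_bin_labels(edges: Sequence[int]) -> tuple[str, ...]:
    """Labels for half-open bins [e_k, e_{k+1}) plus the terminal open bin."""
    labels = [f"{lo}-{hi - 1}" for lo, hi in zip(edges, edges[1:])]
    labels.append(f"{edges[-1]}+")
    return tuple(labels)


@dataclass(frozen=True)
class HarmonizationPolicy:
    """All vocabulary and binning decisions for one audit run.

    ``missing_policy`` is one of ``retain_as_bin`` (missing values become a
    first-class "Not Reported" bin — the default, since missingness is
    itself a salient feature of the compared populations), ``drop``
    (records with a missing value are excluded from that category's
    tabulation), or ``impute_non_hispanic`` (ethnicity only: unreported
    ethnicity is treated as non-Hispanic, the deterministic assumption
    proposed for surveillance data).
    """

    age_bin_edges: tuple[int, ...] = DEFAULT_AGE_EDGES
    missing_policy: str = RETAIN_AS_BIN
    sex_vocab: Mapping[str, str] = field(default_factory=_default_sex_vocab)
    race_vocab: Mapping[str, str] = field(default_factory=_default_race_vocab)
    ethnicity_vocab: Mapping[str, str] = field(default_factory=_default_ethnicity_vocab)
    combined_label_format: str = "Non-Hispanic {race}"
    not_reported_label: str = NOT_REPORTED

    def __post_init__(self) -> None:
        if self.missing_policy not in (RETAIN_AS_BIN, DROP, IMPUTE_NON_HISPANIC):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")
        if not self.age_bin_edges or self.age_bin_edges[0] != 0:
            raise ValueError("age_bin_edges must start at 0")
        if any(b <= a for a, b in zip(self.age_bin_edges, self.age_bin_edges[1:])):
            raise ValueError("age_bin_edges must be strictly increasing")

    def _with_missing(self, labels: Sequence[str]) -> tuple[str, ...]:
        if self.missing_policy == DROP:
            return tuple(labels)
        return tuple(labels) + (self.not_reported_label,)

    def schema_for(self, category: str) -> DemographicSchema:
        """Canonical :class:`DemographicSchema` for one of the five categories."""
        if category == "age_at_index":
            return DemographicSchema(
                category,
                self._with_missing(age_bin_labels(self.age_bin_edges)),
                age_bin_edges=self.age_bin_edges,
                not_reported_label=self.not_reported_label,
            )
        if category == "sex":
            labels = tuple(dict.fromkeys(self.sex_vocab.values()))
            return DemographicSchema(
                category, self._with_missing(labels), not_reported_label=self.not_reported_label
            )
        if category == "race":
            labels = tuple(dict.fromkeys(self.race_vocab.values()))
            return DemographicSchema(
                category, self._with_missing(labels), not_reported_label=self.not_reported_label
            )
        if category == "ethnicity":
            labels = tuple(dict.fromkeys(self.ethnicity_vocab.values()))
            if self.missing_policy == IMPUTE_NON_HISPANIC:
                return DemographicSchema(
                    category, labels, not_reported_label=self.not_reported_label
                )
            return DemographicSchema(
                category, self._with_missing(labels), not_reported_label=self.not_reported_label
            )
        if category == "race_ethnicity":
            return DemographicSchema(
                category,
                self.combined_labels(),
                not_reported_label=self.not_reported_label,
            )
        raise ValueError(f"unknown category {category!r}")

    def combined_labels(self) -> tuple[str, ...]:
        """Ordered label set of the OMB combined race/ethnicity category."""
        races = tuple(dict.fromkeys(self.race_vocab.values()))
        labels = [HISPANIC]
        labels.extend(self.combined_label_format.format(race=r) for r in races)
        if self.missing_policy != DROP:
            labels.append(self.combined_label_format.format(race=self.not_reported_label))
            if self.missing_policy != IMPUTE_NON_HISPANIC:
                labels.append(self.not_reported_label)
        return tuple(labels)

    def to_dict(self) -> dict:
        return {
            "age_bin_edges": list(self.age_bin_edges),
            "missing_policy": self.missing_policy,
            "sex_vocab": dict(self.sex_vocab),
            "race_vocab": dict(self.race_vocab),
            "ethnicity_vocab": dict(self.ethnicity_vocab),
            "combined_label_format": self.combined_label_format,
            "not_reported_label": self.not_reported_label,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "HarmonizationPolicy":
        kwargs = dict(data)
        if "age_bin_edges" in kwargs:
            kwargs["age_bin_edges"] = tuple(int(e) for e in kwargs["age_bin_edges"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "HarmonizationPolicy":
        with open(path, "r", encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)

    def with_missing_policy(self, missing_policy: str) -> "HarmonizationPolicy":
        return replace(self, missing_policy=missing_policy)


def bin_age(age_years: int, edges: Sequence[int] = DEFAULT_AGE_EDGES) -> str:
    """Label of the half-open interval [edges[k], edges[k+1]) containing the age.

    Ages at or above the last edge map to the terminal open-ended bin
    (e.g. ``"80+"``).
    """
    if age_years < 0:
        raise ValueError(f"age must be non-negative, got {age_years}")
    labels = age_bin_labels(edges)
    for k, (lo, hi) in enumerate(zip(edges, edges[1:])):
        if lo <= age_years < hi:
            return labels[k]
    return labels[-1]


def harmonize_value(
    raw: str | None,
    vocab: Mapping[str, str],
    missing_policy: str = RETAIN_AS_BIN,
    not_reported_label: str = NOT_REPORTED,
    unmapped_tally: Counter | None = None,
) -> str | None:
    """Map a raw demographic string to its canonical label.

    Lookup is case-insensitive.  Unmapped non-empty values map to the
    not-reported label and are recorded in ``unmapped_tally`` (and a
    warning log).  Empty/None values follow ``missing_policy``: ``drop``
    returns ``None`` (the record is excluded from the tabulation), every
    other policy returns the not-reported label.  Total by design — never
    raises for any string input.
    """
    text = "" if raw is None else str(raw).strip()
    if not text:
        return None if missing_policy == DROP else not_reported_label
    canonical = vocab.get(text.casefold())
    if canonical is None:
        if unmapped_tally is not None:
            unmapped_tally[text] += 1
        logger.warning("unmapped demographic value %r -> %r", text, not_reported_label)
        return not_reported_label
    return canonical


def combine_race_ethnicity(
    race: str, ethnicity: str, policy: HarmonizationPolicy
) -> str:
    """OMB combined category: Hispanic as one group, non-Hispanic by race.

    Under ``impute_non_hispanic`` an unreported ethnicity is treated as
    non-Hispanic; under the default ``retain_as_bin`` it stays
    "Not Reported".  A non-Hispanic patient with unreported race is
    "Non-Hispanic Not Reported".
    """
    nr = policy.not_reported_label
    if ethnicity == HISPANIC:
        return HISPANIC
    if ethnicity == nr and policy.missing_policy != IMPUTE_NON_HISPANIC:
        return nr
    # ethnicity is Non-Hispanic, or Not Reported imputed to Non-Hispanic
    return policy.combined_label_format.format(race=race)


def _record_label(
    record: PatientRecord,
    category: str,
    policy: HarmonizationPolicy,
    tally: Counter,
) -> str | None:
    if category == "age_at_index":
        if record.age_at_index is None:
            return None if policy.missing_policy == DROP else policy.not_reported_label
        return bin_age(record.age_at_index, policy.age_bin_edges)
    if category == "sex":
        return harmonize_value(
            record.sex, policy.sex_vocab, policy.missing_policy,
            policy.not_reported_label, tally,
        )
    if category == "race":
        return harmonize_value(
            record.race, policy.race_vocab, policy.missing_policy,
            policy.not_reported_label, tally,
        )
    if category == "ethnicity":
        label = harmonize_value(
            record.ethnicity, policy.ethnicity_vocab, RETAIN_AS_BIN,
            policy.not_reported_label, tally,
        )
        if label == policy.not_reported_label:
            if policy.missing_policy == DROP:
                return None
            if policy.missing_policy == IMPUTE_NON_HISPANIC:
                return NON_HISPANIC
        return label
    if category == "race_ethnicity":
        race = harmonize_value(
            record.race, policy.race_vocab, RETAIN_AS_BIN,
            policy.not_reported_label, tally,
        )
        ethnicity = harmonize_value(
            record.ethnicity, policy.ethnicity_vocab, RETAIN_AS_BIN,
            policy.not_reported_label, tally,
        )
        if policy.missing_policy == DROP and (
            ethnicity == policy.not_reported_label
            or (ethnicity != HISPANIC and race == policy.not_reported_label)
        ):
            return None
        return combine_race_ethnicity(race, ethnicity, policy)
    raise ValueError(f"unknown category {category!r}")


def tabulate(
    records: Sequence[PatientRecord],
    category: str | DemographicSchema,
    policy: HarmonizationPolicy | None = None,
) -> CategoricalDistribution:
    """Tabulate harmonized records into a distribution over canonical bins.

    With ``retain_as_bin`` the total count equals the number of input
    records; with ``drop`` it equals the records whose value was reported.
    """
    if not records:
        raise DegenerateInputError("cannot tabulate an empty record list")
    policy = policy or HarmonizationPolicy()
    schema = policy.schema_for(category) if isinstance(category, str) else category
    category_name = schema.category_name
    tally: Counter = Counter()
    counts = {lab: 0.0 for lab in schema.bin_labels}
    dropped = 0
    for record in records:
        label = _record_label(record, category_name, policy, tally)
        if label is None:
            dropped += 1
            continue
        if label not in counts:
            raise ValueError(
                f"harmonized label {label!r} outside schema for {category_name!r}"
            )
        counts[label] += 1
    if tally:
        logger.warning(
            "%d unmapped raw value(s) in category %s: %s",
            sum(tally.values()), category_name, dict(tally),
        )
    if dropped:
        logger.info("dropped %d record(s) with missing %s", dropped, category_name)
    if sum(counts.values()) == 0:
        raise DegenerateInputError(
            f"no records left to tabulate for {category_name!r} after drop policy"
        )
    return counts_to_distribution(
        schema.bin_labels, [counts[lab] for lab in schema.bin_labels]
    )


def positive_records(records: Sequence[PatientRecord]) -> list[PatientRecord]:
    """Records with confirmed positive COVID-19 status.

    Records with unknown status belong in all-patients tabulations but
    never in positive-only ones.
    """
    return [r for r in records if r.covid_status == COVID_POSITIVE]
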