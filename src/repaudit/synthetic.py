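"""Synthetic cohorts, census snapshots and surveillance series with known truth.

The generator emulates the data shapes of a multi-site medical-imaging
data commons audit: patient-level records accruing over ingestion dates,
a decennial-census-style snapshot of the general population, and a
surveillance-style cumulative case-count series.  Demographic values are
drawn from configurable categorical marginals and then masked to
"Not Reported" at per-category rates, so the ground truth stays known and
missingness effects can be studied (cohort-style missingness around 10%,
surveillance-style missingness of 30-45% for race/ethnicity).

Also includes a simplified stratified sequestration splitter that
withholds ~20% of unique patients per stratum, mirroring the open /
sequestered partition contract of a curated data commons.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohort import (
    COVID_NEGATIVE,
    COVID_POSITIVE,
    CategoricalDistribution,
    DemographicSchema,
    PatientRecord,
    ReferenceTable,
    ValidationError,
    counts_to_distribution,
)
from .divergence import js_divergence
from .harmonize import (
    HarmonizationPolicy,
    age_bin_labels,
    combine_race_ethnicity,
    tabulate,
)

_MAX_SEED = 2**31 - 1

# Rough 2020-decennial-style truth marginals used by the default scenario.
DEFAULT_AGE_MARGINAL = {
    "0-9": 0.120, "10-19": 0.130, "20-29": 0.135, "30-39": 0.135,
    "40-49": 0.122, "50-59": 0.128, "60-69": 0.116, "70-79": 0.073,
    "80+": 0.041,
}
DEFAULT_SEX_MARGINAL = {"Male": 0.493, "Female": 0.507}
DEFAULT_RACE_MARGINAL = {
    "White": 0.616, "Black": 0.124, "Asian": 0.060,
    "American Indian or Alaska Native": 0.011,
    "Native Hawaiian or Other Pacific Islander": 0.002,
    "Other": 0.187,
}
DEFAULT_ETHNICITY_MARGINAL = {"Hispanic": 0.187, "Non-Hispanic": 0.813}

#: Cohort-style missingness: around 10% of race/ethnicity unreported.
DEFAULT_COHORT_NOT_REPORTED = {"race": 0.10, "ethnicity": 0.10}
#: Surveillance-style missingness: over 30% race, over 40% ethnicity unreported.
DEFAULT_SURVEILLANCE_NOT_REPORTED = {"race": 0.35, "ethnicity": 0.45}

DEFAULT_COVID_POSITIVE_RATE = 0.55


def _as_dist(marginal: Mapping[str, float] | CategoricalDistribution) -> CategoricalDistribution:
    if isinstance(marginal, CategoricalDistribution):
        return marginal
    return counts_to_distribution(tuple(marginal), tuple(marginal.values()))


@dataclass(frozen=True)
class CohortSpec:
    """Ground-truth recipe for a synthetic patient cohort.

    Each demographic is drawn independently from its marginal, then masked
    to unreported at the category's ``not_reported_rates`` entry.  COVID-19
    status is Bernoulli(``covid_positive_rate``); when
    ``positive_marginals`` are given, positives draw their demographics
    from those marginals instead (letting the positive subpopulation
    differ from the cohort at large).  Batch dates are multinomial over
    ``accrual_weights``.
    """

    n_patients: int
    category_marginals: Mapping[str, CategoricalDistribution]
    covid_positive_rate: float = DEFAULT_COVID_POSITIVE_RATE
    positive_marginals: Mapping[str, CategoricalDistribution] | None = None
    not_reported_rates: Mapping[str, float] = field(default_factory=dict)
    batch_dates: tuple[_dt.date, ...] = (_dt.date(2021, 1, 1),)
    accrual_weights: tuple[float, ...] = (1.0,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValidationError("n_patients must be positive")
        if not (0 <= self.covid_positive_rate <= 1):
            raise ValidationError("covid_positive_rate must be in [0, 1]")
        for cat, rate in self.not_reported_rates.items():
            if not (0 <= rate <= 1):
                raise ValidationError(f"not_reported_rate for {cat!r} must be in [0, 1]")
        if len(self.batch_dates) != len(self.accrual_weights):
            raise ValidationError("batch_dates and accrual_weights length mismatch")
        if abs(sum(self.accrual_weights) - 1.0) > 1e-9:
            raise ValidationError("accrual_weights must sum to 1")
        if any(b <= a for a, b in zip(self.batch_dates, self.batch_dates[1:])):
            raise ValidationError("batch_dates must be strictly increasing")


def default_cohort_spec(
    n_patients: int = 10_000,
    seed: int = 0,
    n_batches: int = 8,
    covid_positive_rate: float = DEFAULT_COVID_POSITIVE_RATE,
    not_reported_rates: Mapping[str, float] | None = None,
) -> CohortSpec:
    """Default synthetic scenario: census-like truth marginals, quarterly
    accrual over ``n_batches`` ingestion dates, ~10% unreported race and
    ethnicity."""
    dates = tuple(
        _dt.date(2020, 9, 1) + _dt.timedelta(days=91 * k) for k in range(n_batches)
    )
    weights = tuple(1.0 / n_batches for _ in range(n_batches))
    # nudge weights to sum exactly to 1
    weights = tuple(w / sum(weights) for w in weights)
    return CohortSpec(
        n_patients=n_patients,
        category_marginals={
            "age_at_index": _as_dist(DEFAULT_AGE_MARGINAL),
            "sex": _as_dist(DEFAULT_SEX_MARGINAL),
            "race": _as_dist(DEFAULT_RACE_MARGINAL),
            "ethnicity": _as_dist(DEFAULT_ETHNICITY_MARGINAL),
        },
        covid_positive_rate=covid_positive_rate,
        not_reported_rates=dict(
            DEFAULT_COHORT_NOT_REPORTED if not_reported_rates is None else not_reported_rates
        ),
        batch_dates=dates,
        accrual_weights=weights,
        seed=seed,
    )


def _age_from_bin(label: str, edges: Sequence[int], rng: np.random.Generator) -> int:
    labels = age_bin_labels(edges)
    k = labels.index(label)
    if k < len(edges) - 1:
        return int(rng.integers(edges[k], edges[k + 1]))
    return int(rng.integers(edges[-1], min(edges[-1] + 21, 121)))


def _draw_category(
    dist: CategoricalDistribution, size: int, rng: np.random.Generator
) -> list[str]:
    idx = rng.choice(len(dist.labels), size=size, p=dist.masses)
    return [dist.labels[i] for i in idx]


def generate_cohort(
    spec: CohortSpec,
    policy: HarmonizationPolicy | None = None,
) -> list[PatientRecord]:
    """Draw a fully reproducible synthetic cohort from its spec.

    The returned records carry canonical-looking raw strings (so the
    default harmonization vocabularies map them), with masked values
    emitted as empty strings, exactly as a contributor table with missing
    fields would look.
    """
    policy = policy or HarmonizationPolicy()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    positive = rng.random(n) < spec.covid_positive_rate

    def marginal_for(cat: str, is_positive: bool) -> CategoricalDistribution:
        if is_positive and spec.positive_marginals and cat in spec.positive_marginals:
            return spec.positive_marginals[cat]
        return spec.category_marginals[cat]

    values: dict[str, list[str]] = {}
    for cat in ("age_at_index", "sex", "race", "ethnicity"):
        if cat not in spec.category_marginals:
            values[cat] = [""] * n
            continue
        base = _draw_category(marginal_for(cat, False), n, rng)
        if spec.positive_marginals and cat in (spec.positive_marginals or {}):
            alt = _draw_category(marginal_for(cat, True), n, rng)
            base = [a if p else b for p, a, b in zip(positive, alt, base)]
        rate = spec.not_reported_rates.get(cat, 0.0)
        if rate > 0:
            mask = rng.random(n) < rate
            base = ["" if m else v for m, v in zip(mask, base)]
        values[cat] = base

    date_idx = rng.choice(len(spec.batch_dates), size=n, p=np.asarray(spec.accrual_weights))

    records = []
    for i in range(n):
        age_label = values["age_at_index"][i]
        age = (
            None
            if not age_label
            else _age_from_bin(age_label, policy.age_bin_edges, rng)
        )
        records.append(
            PatientRecord(
                patient_id=f"P{i:07d}",
                age_at_index=age,
                sex=values["sex"][i],
                race=values["race"][i],
                ethnicity=values["ethnicity"][i],
                covid_status=COVID_POSITIVE if positive[i] else COVID_NEGATIVE,
                batch_date=spec.batch_dates[int(date_idx[i])],
                site_id=f"S{int(rng.integers(1, 6)):02d}",
            )
        )
    return records


def largest_remainder_counts(masses: np.ndarray, total: int) -> np.ndarray:
    """Integer counts of given total proportional to masses (largest remainder)."""
    raw = masses * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def generate_census(
    marginal: Mapping[str, float] | CategoricalDistribution,
    total: int,
    schema: "DemographicSchema | None" = None,
) -> ReferenceTable:
    """Snapshot reference table with integer counts summing exactly to ``total``.

    When ``schema`` is given the snapshot is laid out over its full bin
    label set (absent labels get count 0), so it aligns label-for-label
    with cohort tabulations under the same harmonization policy.
    """
    if total <= 0:
        raise ValidationError("census total must be positive")
    dist = _as_dist(marginal)
    n_positive = int(np.count_nonzero(dist.masses > 0))
    if total < n_positive:
        raise ValidationError(
            f"total {total} below the {n_positive} bins with positive mass; "
            "counts would round to zero"
        )
    counts = largest_remainder_counts(dist.masses, total)
    snapshot = counts_to_distribution(dist.labels, counts.tolist())
    if schema is None:
        schema = DemographicSchema("census", dist.labels)
    else:
        snapshot = snapshot.reindexed(schema.bin_labels)
    return ReferenceTable(kind="snapshot", schema=schema, snapshot=snapshot)


def generate_surveillance(
    truth_marginal: Mapping[str, float] | CategoricalDistribution,
    dates: Sequence[_dt.date],
    per_date_totals: Sequence[int],
    not_reported_rate: float = 0.0,
    seed: int = 0,
    not_reported_label: str = "Not Reported",
    schema: "DemographicSchema | None" = None,
) -> ReferenceTable:
    """Cumulative surveillance-style series with multinomial per-date increments.

    Each increment is drawn from the truth marginal with Not-Reported
    masking (a fraction ``not_reported_rate`` of each increment is
    reassigned to the not-reported bin before drawing), so per-label
    cumulative counts are non-decreasing by construction.
    """
    dist = _as_dist(truth_marginal)
    totals = [int(t) for t in per_date_totals]
    if len(totals) != len(dates):
        raise ValidationError("dates and per_date_totals length mismatch")
    if any(b < a for a, b in zip(totals, totals[1:])):
        raise ValidationError("per_date_totals must be non-decreasing")
    if not (0 <= not_reported_rate <= 1):
        raise ValidationError("not_reported_rate must be in [0, 1]")

    labels = list(dist.labels)
    masses = dist.masses.copy()
    if not_reported_rate > 0:
        if not_reported_label not in labels:
            labels.append(not_reported_label)
            masses = np.append(masses, 0.0)
        nr = labels.index(not_reported_label)
        masses = masses * (1.0 - not_reported_rate)
        masses[nr] += not_reported_rate
    labels_t = tuple(labels)

    rng = np.random.default_rng(seed)
    cumulative = np.zeros(len(labels_t), dtype=float)
    series = []
    prev_total = 0
    for date, total in zip(dates, totals):
        increment = total - prev_total
        if increment > 0:
            cumulative += rng.multinomial(increment, masses)
        prev_total = total
        dist = CategoricalDistribution(labels_t, tuple(cumulative.tolist()))
        if schema is not None:
            dist = dist.reindexed(schema.bin_labels)
        series.append((date, dist))
    if schema is None:
        schema = DemographicSchema(
            "surveillance", labels_t, not_reported_label=not_reported_label
        )
    return ReferenceTable(kind="cumulative_series", schema=schema, series=tuple(series))


def combined_truth_marginal(
    race_marginal: Mapping[str, float] | CategoricalDistribution,
    ethnicity_marginal: Mapping[str, float] | CategoricalDistribution,
    policy: HarmonizationPolicy | None = None,
) -> CategoricalDistribution:
    """OMB combined race/ethnicity truth implied by independent marginals."""
    policy = policy or HarmonizationPolicy()
    race = _as_dist(race_marginal)
    eth = _as_dist(ethnicity_marginal)
    combined: dict[str, float] = {}
    for e_lab, e_mass in zip(eth.labels, eth.masses):
        for r_lab, r_mass in zip(race.labels, race.masses):
            label = combine_race_ethnicity(r_lab, e_lab, policy)
            combined[label] = combined.get(label, 0.0) + e_mass * r_mass
    return counts_to_distribution(tuple(combined), tuple(combined.values()))


@dataclass(frozen=True)
class SplitResult:
    """Open/sequestered partition of a cohort with per-stratum realized fractions."""

    open_set: tuple[PatientRecord, ...]
    sequestered_set: tuple[PatientRecord, ...]
    per_stratum_fractions: Mapping[tuple[str, ...], float]

    @property
    def open_fraction(self) -> float:
        total = len(self.open_set) + len(self.sequestered_set)
        return len(self.open_set) / total if total else 0.0


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def sequestration_split(
    records: Sequence[PatientRecord],
    strata_categories: Sequence[str],
    open_fraction: float = 0.8,
    seed: int = 0,
    policy: HarmonizationPolicy | None = None,
) -> SplitResult:
    """Stratified open/sequestered split of unique patients.

    Strata are the cross-product of the harmonized bins of
    ``strata_categories``.  Within each stratum the open quota is
    ``round(open_fraction * stratum_size)`` (half away from zero) and
    membership is drawn at random by ``seed``, so the realized overall
    open fraction agrees with ``open_fraction`` to within per-stratum
    rounding.  A simplified, transparent stand-in for a production
    multidimensional sequestration algorithm.
    """
    if not (0 < open_fraction <= 1):
        raise ValidationError("open_fraction must be in (0, 1]")
    if not records:
        return SplitResult((), (), {})
    policy = policy or HarmonizationPolicy()
    from .harmonize import _record_label  # single point of truth for binning
    from collections import Counter

    tally: Counter = Counter()
    strata: dict[tuple[str, ...], list[int]] = {}
    for i, record in enumerate(records):
        key = tuple(
            str(_record_label(record, cat, policy, tally)) for cat in strata_categories
        )
        strata.setdefault(key, []).append(i)

    rng = np.random.default_rng(seed)
    open_idx: set[int] = set()
    fractions: dict[tuple[str, ...], float] = {}
    for key in sorted(strata):
        members = strata[key]
        quota = _round_half_away(open_fraction * len(members))
        chosen = rng.permutation(len(members))[:quota]
        for c in chosen:
            open_idx.add(members[int(c)])
        fractions[key] = quota / len(members)

    open_set = tuple(r for i, r in enumerate(records) if i in open_idx)
    seq_set = tuple(r for i, r in enumerate(records) if i not in open_idx)
    return SplitResult(open_set, seq_set, fractions)


def recovery_scenario(
    truth_marginal: Mapping[str, float] | CategoricalDistribution,
    n_grid: Sequence[int],
    seed: int = 0,
    category: str = "sex",
    policy: HarmonizationPolicy | None = None,
) -> list[float]:
    """Pipeline validation: JSD between sampled cohorts and their own truth.

    For each n, a cohort of n patients is drawn from ``truth_marginal``
    for ``category`` (no masking), tabulated through the harmonization
    path, and compared to the truth with the JSD.  As n grows the JSD
    should fall toward 0 — the sampling-convergence property the audit
    relies on to interpret small JSD values as genuine representativeness.
    """
    policy = policy or HarmonizationPolicy()
    truth = _as_dist(truth_marginal)
    out = []
    for k, n in enumerate(n_grid):
        spec = CohortSpec(
            n_patients=int(n),
            category_marginals={category: truth},
            covid_positive_rate=0.5,
            seed=(seed + 7919 * k) % _MAX_SEED,
        )
        cohort = generate_cohort(spec, policy)
        observed = tabulate(cohort, category, policy)
        truth_full = truth.reindexed(observed.labels)
        out.append(js_divergence(observed, truth_full, 2).jsd)
    return out
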