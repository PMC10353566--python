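"""Index-event deduplication, cumulative timelines, and the comparison series."""

import datetime as dt
import math
import random

import pytest

from repaudit import (
    DemographicSchema,
    HarmonizationPolicy,
    ReferenceTable,
    build_timeline,
    comparison_series,
    counts_to_distribution,
    deduplicate_to_index,
    interpret_delta,
    js_divergence,
    jsd_delta,
    tabulate,
)
from repaudit.cohort import ValidationError
from repaudit.longitudinal import (
    DELTA_NEGATIVE_LABEL,
    DELTA_POSITIVE_LABEL,
)

from conftest import make_record

D1, D2, D3 = dt.date(2021, 1, 1), dt.date(2021, 2, 1), dt.date(2021, 3, 1)


class TestDeduplicateToIndex:
    def test_earliest_batch_date_demographics_win(self):
        late = make_record(patient_id="P", race="Black", batch_date=D2)
        early = make_record(patient_id="P", race="White", batch_date=D1)
        result = deduplicate_to_index([late, early])
        assert len(result) == 1
        assert result[0].race == "White" and result[0].batch_date == D1

    def test_all_unique_input_unchanged(self):
        records = [make_record(patient_id=f"P{i}") for i in range(5)]
        assert deduplicate_to_index(records) == records

    def test_empty_input(self):
        assert deduplicate_to_index([]) == []

    def test_same_date_tie_keeps_first_in_input_order(self):
        a = make_record(patient_id="P", race="White", batch_date=D1)
        b = make_record(patient_id="P", race="Black", batch_date=D1)
        assert deduplicate_to_index([a, b])[0].race == "White"


class TestBuildTimeline:
    def test_cumulative_cohort_sizes(self):
        records = [make_record(patient_id=f"A{i}", batch_date=D1) for i in range(2)]
        records += [make_record(patient_id=f"B{i}", batch_date=D2) for i in range(3)]
        timeline = build_timeline(records, [D1, D2])
        assert [len(c) for c in timeline.cohorts] == [2, 5]

    def test_nesting_is_monotone(self):
        records = [
            make_record(patient_id=f"P{i}", batch_date=random.Random(1).choice([D1, D2, D3]))
            for i in range(20)
        ]
        timeline = build_timeline(records, [D1, D2, D3])
        sizes = [len(c) for c in timeline.cohorts]
        assert sizes == sorted(sizes)
        ids_prev = set()
        for cohort in timeline.cohorts:
            ids = {r.patient_id for r in cohort}
            assert ids_prev <= ids
            assert len(ids) == len(cohort)  # unique per date
            ids_prev = ids

    def test_date_before_all_batches_gives_empty_cohort(self):
        records = [make_record(batch_date=D2)]
        timeline = build_timeline(records, [D1, D2])
        assert len(timeline.cohorts[0]) == 0

    def test_boundary_date_included(self):
        records = [make_record(batch_date=D2)]
        timeline = build_timeline(records, [D2])
        assert len(timeline.cohorts[0]) == 1

    def test_unsorted_dates_rejected(self):
        with pytest.raises(ValidationError):
            build_timeline([make_record()], [D2, D1])

    def test_positives_exclude_unknown_status(self):
        records = [
            make_record(patient_id="A", covid_status="positive"),
            make_record(patient_id="B", covid_status="negative"),
            make_record(patient_id="C", covid_status="unknown"),
        ]
        timeline = build_timeline(records, [D1])
        assert len(timeline.cohorts[0]) == 3
        assert [r.patient_id for r in timeline.positives[0]] == ["A"]


class TestJsdDelta:
    @pytest.mark.parametrize("a,p,expected", [(0.3, 0.3, 0.0), (0.1, 0.3, -0.2), (0.3, 0.1, 0.2)])
    def test_signed_difference(self, a, p, expected):
        assert jsd_delta(a, p) == pytest.approx(expected)

    def test_negative_means_all_patients_more_representative(self):
        assert interpret_delta(-0.2) == DELTA_NEGATIVE_LABEL

    def test_positive_means_positives_more_representative(self):
        assert interpret_delta(0.2) == DELTA_POSITIVE_LABEL


def _references(policy, all_counts, surv_counts_by_date):
    schema = policy.schema_for("sex")
    census = ReferenceTable(
        kind="snapshot",
        schema=schema,
        snapshot=counts_to_distribution(schema.bin_labels, all_counts),
    )
    series = tuple(
        (date, counts_to_distribution(schema.bin_labels, counts))
        for date, counts in surv_counts_by_date
    )
    surveillance = ReferenceTable(kind="cumulative_series", schema=schema, series=series)
    return census, surveillance


class TestComparisonSeries:
    def records(self):
        recs = [
            make_record(patient_id=f"A{i}", sex="Male" if i % 2 else "Female",
                        covid_status="positive", batch_date=D1)
            for i in range(4)
        ]
        recs += [
            make_record(patient_id=f"B{i}", sex="Male" if i % 2 else "Female",
                        covid_status="negative", batch_date=D2)
            for i in range(4)
        ]
        return recs

    def test_surveillance_equal_to_census_proportions_gives_zero_reference_jsd(self, policy):
        records = self.records()
        timeline = build_timeline(records, [D1, D2])
        census, surveillance = _references(
            policy,
            (500, 500, 0, 0),
            [(D1, (50, 50, 0, 0)), (D2, (80, 80, 0, 0))],
        )
        series = comparison_series(timeline, census, surveillance, "sex", policy)
        assert series.jsd_surveillance_vs_census == (0.0, 0.0)
        # cohort drawn 50/50 exactly matches census proportions too
        assert series.jsd_all_vs_census == (0.0, 0.0)
        assert series.delta == (0.0, 0.0)

    def test_single_date_series_matches_direct_divergence_call(self, policy):
        records = [r for r in self.records() if r.batch_date == D1]
        timeline = build_timeline(records, [D1])
        census, surveillance = _references(
            policy, (300, 700, 0, 0), [(D1, (40, 60, 0, 0))]
        )
        series = comparison_series(timeline, census, surveillance, "sex", policy)
        assert len(series.dates) == 1
        all_dist = tabulate(records, "sex", policy)
        expected_all = js_divergence(all_dist, census.snapshot).jsd
        assert series.jsd_all_vs_census[0] == pytest.approx(expected_all, abs=1e-15)
        pos = [r for r in records if r.covid_status == "positive"]
        expected_pos = js_divergence(tabulate(pos, "sex", policy), surveillance.series[0][1]).jsd
        assert series.jsd_pos_vs_surveillance[0] == pytest.approx(expected_pos, abs=1e-15)

    def test_delta_identity_holds_per_date(self, policy):
        timeline = build_timeline(self.records(), [D1, D2])
        census, surveillance = _references(
            policy, (300, 700, 0, 0), [(D1, (40, 60, 0, 0)), (D2, (70, 90, 0, 0))]
        )
        series = comparison_series(timeline, census, surveillance, "sex", policy)
        for a, p, d in zip(series.jsd_all_vs_census, series.jsd_pos_vs_surveillance, series.delta):
            assert d == pytest.approx(a - p, abs=1e-12)

    def test_permutation_invariance_of_series(self, policy):
        records = self.records()
        shuffled = records[:]
        random.Random(7).shuffle(shuffled)
        census, surveillance = _references(
            policy, (300, 700, 0, 0), [(D1, (40, 60, 0, 0)), (D2, (70, 90, 0, 0))]
        )
        s1 = comparison_series(build_timeline(records, [D1, D2]), census, surveillance, "sex", policy)
        s2 = comparison_series(build_timeline(shuffled, [D1, D2]), census, surveillance, "sex", policy)
        assert s1 == s2

    def test_timeline_before_surveillance_coverage_error(self, policy):
        timeline = build_timeline(self.records(), [D1, D2])
        census, surveillance = _references(policy, (300, 700, 0, 0), [(D2, (40, 60, 0, 0))])
        with pytest.raises(ValidationError):
            comparison_series(timeline, census, surveillance, "sex", policy)

    def test_surveillance_lookup_uses_nearest_preceding_date(self, policy):
        records = self.records()
        # second timeline date D3 has no exact surveillance entry; D2's is used
        timeline = build_timeline(records, [D1, D3])
        census, surveillance = _references(
            policy, (300, 700, 0, 0), [(D1, (40, 60, 0, 0)), (D2, (70, 90, 0, 0))]
        )
        series = comparison_series(timeline, census, surveillance, "sex", policy)
        pos = [r for r in records if r.covid_status == "positive"]
        expected = js_divergence(tabulate(pos, "sex", policy), surveillance.series[1][1]).jsd
        assert series.jsd_pos_vs_surveillance[1] == pytest.approx(expected, abs=1e-15)

    def test_no_positives_yields_nan_delta(self, policy):
        records = [make_record(patient_id="A", covid_status="negative", batch_date=D1)]
        timeline = build_timeline(records, [D1])
        census, surveillance = _references(policy, (300, 700, 0, 0), [(D1, (40, 60, 0, 0))])
        series = comparison_series(timeline, census, surveillance, "sex", policy)
        assert math.isnan(series.jsd_pos_vs_surveillance[0])
        assert math.isnan(series.delta[0])
        assert "undefined" in interpret_delta(series.delta[0])
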