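"""%LN+ computation, cohort filtering, cutoff scan and group stratification."""

import math

import numpy as np
import pytest

from nodestrat import (
    CohortSpec,
    DataIntegrityError,
    StratumSpec,
    cutoff_scan,
    filter_cohort,
    generate_cohort,
    percent_ln_positive,
    stratify_by_ln_count,
    stratify_groups,
)

from conftest import make_record


class TestPercentLnPositive:
    @pytest.mark.parametrize(
        "pos,ex,expected",
        [(1, 20, 0.05), (4, 10, 0.40), (0, 12, 0.0), (9, 9, 1.0)],
    )
    def test_values(self, pos, ex, expected):
        rec = make_record(nodes_positive=pos, nodes_examined=ex)
        assert percent_ln_positive(rec) == pytest.approx(expected)

    def test_zero_examined_signals_exclusion(self):
        rec = make_record(nodes_examined=0, nodes_positive=0)
        assert math.isnan(percent_ln_positive(rec))

    def test_integrity_error(self):
        rec = make_record(nodes_examined=10, nodes_positive=2)
        object.__setattr__(rec, "nodes_positive", 12)  # corrupt post-validation
        with pytest.raises(DataIntegrityError):
            percent_ln_positive(rec)


class TestFilterCohort:
    def test_empty_criteria_is_identity(self, small_cohort):
        assert filter_cohort(small_cohort) == list(small_cohort)

    def test_matches_brute_force(self, small_cohort):
        got = filter_cohort(small_cohort, ln_positive_required=True,
                            race="white", grade="III", radiation="no")
        expected = [
            r for r in small_cohort
            if r.nodes_positive >= 1 and r.race == "white"
            and r.grade == "III" and r.radiation == "no"
        ]
        assert got == expected
        assert 0 < len(got) < len(small_cohort)

    def test_unknowns_excluded_when_filtered(self):
        cohort = [make_record(patient_id="u", grade="unknown"),
                  make_record(patient_id="g3", grade="III")]
        assert [r.patient_id for r in filter_cohort(cohort, grade="III")] == ["g3"]

    def test_empty_result_warns(self):
        cohort = [make_record(grade="III"), make_record(grade="II")]
        with pytest.warns(UserWarning, match="exclude"):
            out = filter_cohort(cohort, grade="I")
        assert out == []


class TestCutoffScan:
    def test_full_cutoff_equals_whole_cohort_fit(self, synth_table, small_cohort):
        from nodestrat import fit_group

        rows = cutoff_scan(small_cohort, synth_table, cutoffs=[1.0], seed=4,
                           max_months=120)
        assert len(rows) == 1 and not rows[0].skipped
        ln_pos = [r for r in small_cohort
                  if r.nodes_positive >= 1 and r.nodes_examined >= 1]
        assert rows[0].n == len(ln_pos)
        whole_fit, *_ = fit_group(ln_pos, synth_table, max_months=120, seed=4)
        assert rows[0].fit.to_dict() == whole_fit.to_dict()

    def test_duplicate_cutoffs_identical_rows(self, synth_table, small_cohort):
        rows = cutoff_scan(small_cohort, synth_table, cutoffs=[0.5, 0.5],
                           seed=0, max_months=60)
        assert rows[0].fit.to_dict() == rows[1].fit.to_dict()

    def test_small_subcohort_skipped(self, synth_table, small_cohort):
        rows = cutoff_scan(small_cohort, synth_table, cutoffs=[0.5],
                           min_group=10**6, max_months=60)
        assert rows[0].skipped and rows[0].fit is None
        assert math.isnan(rows[0].ip_years)

    def test_unsorted_or_invalid_cutoffs_rejected(self, synth_table, small_cohort):
        with pytest.raises(ValueError):
            cutoff_scan(small_cohort, synth_table, cutoffs=[0.5, 0.2])
        with pytest.raises(ValueError):
            cutoff_scan(small_cohort, synth_table, cutoffs=[0.0, 0.5])

    def test_two_stratum_truth_recovery(self, synth_table):
        """Two strata with true IPs 25 y (<10% LN+) and 7 y (>=40% LN+):
        scanning at cutoff 0.10 isolates the first stratum and recovers an
        IP near 25 y (wide tolerance: at this n the late IP sits at the
        identifiability edge), while the full-cohort fit at cutoff 1.0 is
        pulled down by the worse stratum."""
        spec = CohortSpec(
            strata=(
                StratumSpec("<10%", (0.0, 0.10), 2000, b1_true=1.0,
                            b2_true=9.016, b3_true=math.log(9.016) / 25.0),
                StratumSpec(">=40%", (0.40, 1.0), 2000, b1_true=0.469,
                            b2_true=4.51, b3_true=math.log(4.51) / 7.0,
                            closed_top=True),
            ),
            seed=0,
        )
        cohort = generate_cohort(spec, synth_table)
        rows = cutoff_scan(cohort, synth_table, cutoffs=[0.10, 1.0], seed=0,
                           max_months=312)
        ip_low, ip_all = rows[0].ip_years, rows[1].ip_years
        assert ip_low == pytest.approx(25.0, rel=0.35)
        assert 7.0 < ip_all < ip_low


class TestStratifyGroups:
    def test_boundary_040_goes_to_top_group(self, synth_table):
        cohort = [
            make_record(patient_id=str(i), nodes_positive=4, nodes_examined=10,
                        follow_up_months=60, vital_status="dead")
            for i in range(10)
        ]
        res = stratify_groups(cohort, synth_table, max_months=24)
        assert res.group(">=40%").n == 10
        assert res.group("<10%").n == 0 and res.group("<10%").fit is None

    def test_partition(self, synth_table, small_cohort):
        res = stratify_groups(small_cohort, synth_table, max_months=60)
        ln_pos = [r for r in small_cohort
                  if r.nodes_positive >= 1 and r.nodes_examined >= 1]
        assert sum(g.n for g in res.groups) == len(ln_pos)

    def test_pairwise_tests_present(self, synth_table, small_cohort):
        res = stratify_groups(small_cohort, synth_table, max_months=120,
                              test_months=(60, 120))
        labels = {g.label for g in res.groups}
        assert labels == {"<10%", "10-40%", ">=40%"}
        assert len(res.pairwise_tests) == 3 * 2  # 3 pairs x 2 months
        assert len(res.logrank_tests) == 3
        for t in res.pairwise_tests:
            assert 0.0 <= t.p <= 1.0

    def test_result_serializes(self, synth_table, small_cohort):
        import json

        res = stratify_groups(small_cohort, synth_table, max_months=60)
        blob = json.dumps(res.to_dict())
        assert "scan_table" in blob


class TestStratifyByLnCount:
    def test_partition_and_class_assignment(self, synth_table, small_cohort):
        res = stratify_by_ln_count(small_cohort, synth_table, max_months=60)
        assert [g.label for g in res.groups] == ["1", "2", "3", ">=4"]
        ln_pos = [r for r in small_cohort
                  if r.nodes_positive >= 1 and r.nodes_examined >= 1]
        assert sum(g.n for g in res.groups) == len(ln_pos)

    def test_counts_4_and_9_share_top_class(self, synth_table):
        cohort = [
            make_record(patient_id="a", nodes_positive=4, nodes_examined=12,
                        follow_up_months=60, vital_status="dead"),
            make_record(patient_id="b", nodes_positive=9, nodes_examined=12,
                        follow_up_months=80, vital_status="dead"),
        ]
        res = stratify_by_ln_count(cohort, synth_table, max_months=24)
        assert res.group(">=4").n == 2
        assert all(g.n == 0 for g in res.groups if g.label != ">=4")
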