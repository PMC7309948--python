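"""Eligibility cascade: index selection, enrollment, cohort assignment."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ibd_claims.codemaps import charlson_score, classify_claims
from ibd_claims.cohort import (
    DX_COLUMNS,
    age_years,
    assign_cohort,
    build_cohort,
    check_enrollment,
    select_index,
)
from ibd_claims.config import SimConfig, StudyConfig
from ibd_claims.pipeline import run_analysis
from ibd_claims.synthetic import generate_population, inject_edge_cases


def _events(rows):
    return pd.DataFrame(
        [dict(person_id=p, event_date=pd.Timestamp(d), drug=drug, route="NDC",
              days_supply=0) for p, d, drug in rows],
        columns=["person_id", "event_date", "drug", "route", "days_supply"],
    )


def _spans(rows):
    return pd.DataFrame(
        [dict(person_id="P1", span_start=pd.Timestamp(a), span_end=pd.Timestamp(b),
              has_medical=True, has_pharmacy=True) for a, b in rows]
    )


class TestSelectIndex:
    def test_earliest_in_window_event_wins(self):
        ev = _events([("P1", "2011-05-01", "adalimumab"), ("P1", "2012-01-01", "infliximab")])
        out = select_index(ev, StudyConfig())
        assert out.iloc[0]["index_drug"] == "adalimumab"
        assert out.iloc[0]["index_date"] == pd.Timestamp("2011-05-01")

    def test_pre_window_only_person_absent(self):
        ev = _events([("P1", "2009-12-01", "adalimumab")])
        assert len(select_index(ev, StudyConfig())) == 0

    def test_same_day_two_drugs_flagged_ambiguous(self):
        ev = _events([("P1", "2011-05-01", "adalimumab"), ("P1", "2011-05-01", "infliximab")])
        out = select_index(ev, StudyConfig())
        assert bool(out.iloc[0]["ambiguous"])
        assert pd.isna(out.iloc[0]["index_drug"])


def _coverage_oracle(spans, index_date, baseline_days, followup_days) -> bool:
    """Day-by-day coverage check over the required window."""
    idx = pd.Timestamp(index_date)
    days = pd.date_range(idx - pd.Timedelta(days=baseline_days),
                         idx + pd.Timedelta(days=followup_days - 1))
    ivs = list(zip(spans["span_start"], spans["span_end"]))
    return all(any(a <= d <= b for a, b in ivs) for d in days)


class TestCheckEnrollment:
    def test_single_covering_span(self):
        spans = _spans([("2010-01-01", "2013-12-31")])
        assert check_enrollment(spans, "2011-06-01", 365, 365)

    def test_followup_gap_fails(self):
        spans = _spans([("2010-01-01", "2011-07-01")])
        assert not check_enrollment(spans, "2011-06-01", 365, 365)

    def test_abutting_spans_count_as_continuous(self):
        spans = _spans([("2010-01-01", "2011-08-31"), ("2011-09-01", "2013-12-31")])
        assert check_enrollment(spans, "2011-06-01", 365, 365)
        assert _coverage_oracle(spans, "2011-06-01", 365, 365)

    def test_missing_benefit_flag_disqualifies(self):
        spans = _spans([("2010-01-01", "2013-12-31")])
        spans["has_pharmacy"] = False
        assert not check_enrollment(spans, "2011-06-01", 365, 365)

    def test_matches_day_by_day_oracle_on_random_span_sets(self):
        rng = np.random.default_rng(42)
        base = pd.Timestamp("2011-06-01")
        for _ in range(150):
            n = rng.integers(1, 4)
            rows = []
            for _ in range(n):
                start = base + pd.Timedelta(days=int(rng.integers(-500, 300)))
                rows.append((start, start + pd.Timedelta(days=int(rng.integers(30, 700)))))
            spans = _spans([(a.date(), b.date()) for a, b in rows])
            assert check_enrollment(spans, base, 365, 365) == _coverage_oracle(
                spans, base, 365, 365)


def _visits(rows):
    return pd.DataFrame(
        [dict(person_id="P1", service_start=pd.Timestamp(d), service_end=pd.Timestamp(d),
              setting="office", dx1=c, dx2=None, dx3=None, dx4=None, hcpcs=None,
              paid_usd=100.0, service_year=2011) for d, c in rows]
    )


class TestAssignCohort:
    def test_majority_rule(self):
        med = _visits([("2011-01-01", "556.9"), ("2011-02-01", "556.1"),
                       ("2011-03-01", "556.9"), ("2011-04-01", "555.9")])
        assert assign_cohort(med) == "UC"

    def test_equal_nonzero_counts_is_tie(self):
        med = _visits([("2011-01-01", "556.9"), ("2011-02-01", "556.9"),
                       ("2011-03-01", "555.9"), ("2011-04-01", "555.9")])
        assert assign_cohort(med) == "tie"

    def test_no_ibd_codes_is_none(self):
        assert assign_cohort(_visits([("2011-01-01", "714.0")])) == "none"
        assert assign_cohort(_visits([])) == "none"

    def test_symmetric_under_relabeling(self):
        rows = [("2011-01-01", "556.9"), ("2011-02-01", "556.9"), ("2011-03-01", "555.9")]
        swap = {"556.9": "555.9", "555.9": "556.9"}
        flipped = [(d, swap[c]) for d, c in rows]
        assert assign_cohort(_visits(rows)) == "UC"
        assert assign_cohort(_visits(flipped)) == "CD"

    def test_same_day_claims_count_one_visit(self):
        med = _visits([("2011-01-01", "556.9"), ("2011-01-01", "556.9"),
                       ("2011-03-01", "555.9"), ("2011-04-01", "555.9")])
        assert assign_cohort(med) == "CD"


class TestBuildCohort:
    def test_edge_patients_excluded_with_expected_reason(self, edge_run, edge_tables):
        ir = edge_run.index_records.set_index("person_id")
        gt = edge_tables.ground_truth.set_index("person_id")
        for pid in gt.index[gt.index.str.startswith("EDGE")]:
            expected = gt.loc[pid, "expected_reason"]
            if expected == "none":
                assert ir.loc[pid, "included"]
            else:
                assert ir.loc[pid, "exclusion_reason"] == expected, pid

    def test_generator_induced_defects_recovered(self, edge_run, edge_tables):
        ir = edge_run.index_records.set_index("person_id")
        gt = edge_tables.ground_truth.set_index("person_id")
        gen = gt[~gt.index.str.startswith("EDGE")]
        both = gen.join(ir[["exclusion_reason", "included"]], how="inner")
        defects = both[both["expected_reason"] != "none"]
        assert (defects["exclusion_reason"] == defects["expected_reason"]).all()

    def test_attrition_counts_are_monotone_and_consistent(self, edge_run):
        att = edge_run.attrition
        assert (att["entering"].diff().dropna() <= 0).all()
        assert (att["passing"] == att["entering"] - att["excluded"]).all()
        assert (att["entering"].iloc[1:].to_numpy() == att["passing"].iloc[:-1].to_numpy()).all()

    def test_two_year_cohort_nested_in_one_year(self, edge_tables):
        r1 = run_analysis(edge_tables, StudyConfig(followup_days=365))
        r2 = run_analysis(edge_tables, StudyConfig(followup_days=730,
                                                   index_window_end="2014-03-31"))
        inc1 = set(r1.index_records.loc[r1.index_records["included"], "person_id"])
        inc2 = set(r2.index_records.loc[r2.index_records["included"], "person_id"])
        assert inc2 <= inc1
        assert len(inc2) < len(inc1)

    def test_empty_input_yields_empty_cohort(self, maps):
        tables = generate_population(SimConfig(n_patients=0, seed=1))
        events = classify_claims(tables.medical, tables.pharmacy, maps)
        ir, att = build_cohort(tables, events, StudyConfig())
        assert len(ir) == 0
        assert (att["entering"] == 0).all()

    def test_matches_per_patient_oracle(self, maps, charlson_map):
        """Vectorized cascade equals a brute-force per-patient oracle."""
        tables = inject_edge_cases(generate_population(SimConfig(n_patients=150, seed=21)))
        events = classify_claims(tables.medical, tables.pharmacy, maps)
        study = StudyConfig()
        ir, _ = build_cohort(tables, events, study)

        demo = tables.enrollment.drop_duplicates("person_id").set_index("person_id")
        for row in ir.itertuples(index=False):
            pid = row.person_id
            idx = pd.Timestamp(row.index_date)
            expected = _oracle_reason(pid, idx, row.index_drug, tables, events, study, demo)
            assert row.exclusion_reason == expected, pid
            if expected == "none":
                med = tables.medical[tables.medical["person_id"] == pid]
                base = med[(med["service_start"] >= idx - pd.Timedelta(days=365))
                           & (med["service_start"] < idx)]
                codes = [c for col in DX_COLUMNS for c in base[col].dropna().astype(str)]
                assert row.charlson == charlson_score(codes, charlson_map)


def _oracle_reason(pid, idx, drug, tables, events, study, demo):
    """First failing stage, evaluated with the scalar per-patient operations."""
    ev = events[events["person_id"] == pid]
    at_first = ev[ev["event_date"] == ev["event_date"].min()]
    if at_first["drug"].nunique() > 1:
        return "ambiguous-index"
    if age_years(demo.loc[pid, "birth_date"], idx) < study.min_age:
        return "age"
    spans = tables.enrollment[tables.enrollment["person_id"] == pid]
    if not check_enrollment(spans, idx, study.baseline_days, study.followup_days):
        return "enrollment"
    med = tables.medical[tables.medical["person_id"] == pid]
    base = med[(med["service_start"] >= idx - pd.Timedelta(days=365))
               & (med["service_start"] <= idx)]
    assigned = assign_cohort(base)
    if assigned == "none":
        return "no-IBD-dx"
    if assigned == "tie":
        return "tie-excluded"
    washout = ev[(ev["event_date"] >= idx - pd.Timedelta(days=365))
                 & (ev["event_date"] < idx)]
    if len(washout):
        return "baseline-biologic"
    fu_hi = idx + pd.Timedelta(days=study.followup_days - 1)
    window = med[(med["service_start"] >= idx - pd.Timedelta(days=365))
                 & (med["service_start"] <= fu_hi)]
    for col in DX_COLUMNS:
        if window[col].astype("string").fillna("").str.startswith(
                tuple(study.cancer_dx_prefixes)).any():
            return "cancer"
    return "none"
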