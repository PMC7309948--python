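"""Utilization rollups, CPI adjustment, cost routing and aggregation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ibd_claims.codemaps import medication_hcpcs
from ibd_claims.outcomes import (
    CpiTable,
    adjust_cost,
    aggregate,
    count_visits,
    roll_up_admissions,
    summarize_patients,
    summarize_window,
)

_W = (pd.Timestamp("2012-01-01"), pd.Timestamp("2012-12-30"))


_MED_COLS = ["claim_id", "person_id", "service_start", "service_end", "setting",
             "dx1", "dx2", "dx3", "dx4", "hcpcs", "paid_usd", "service_year"]
_RX_COLS = ["claim_id", "person_id", "fill_date", "ndc", "days_supply", "paid_usd",
            "service_year"]


def _med(rows):
    return pd.DataFrame(
        [dict(claim_id=f"M{i}", person_id="P1", service_start=pd.Timestamp(a),
              service_end=pd.Timestamp(b), setting=s, dx1=None, dx2=None, dx3=None,
              dx4=None, hcpcs=h, paid_usd=float(p), service_year=pd.Timestamp(a).year)
         for i, (a, b, s, h, p) in enumerate(rows)],
        columns=_MED_COLS,
    )


def _rx(rows):
    return pd.DataFrame(
        [dict(claim_id=f"R{i}", person_id="P1", fill_date=pd.Timestamp(d), ndc=n,
              days_supply=30, paid_usd=float(p), service_year=pd.Timestamp(d).year)
         for i, (d, n, p) in enumerate(rows)],
        columns=_RX_COLS,
    )


_EMPTY_MED = _med([])
_EMPTY_RX = _rx([])


class TestCpi:
    def test_2015_factor_is_identity(self):
        cpi = CpiTable.from_package()
        assert cpi.factor(2015) == pytest.approx(1.0)
        assert cpi.factor(2010) > 1.0  # older dollars inflate upward

    def test_adjust_is_linear(self):
        cpi = CpiTable(factors={2012: 1.2, 2015: 1.0})
        assert adjust_cost(100.0, 2015, cpi) == pytest.approx(100.0)
        assert adjust_cost(100.0, 2012, cpi) == pytest.approx(120.0)
        amounts = [10.0, 25.5, 3.0]
        assert sum(adjust_cost(a, 2012, cpi) for a in amounts) == pytest.approx(
            adjust_cost(sum(amounts), 2012, cpi))

    def test_missing_year_is_hard_error(self):
        cpi = CpiTable(factors={2015: 1.0})
        with pytest.raises(KeyError, match="1999"):
            adjust_cost(1.0, 1999, cpi)


class TestAdmissions:
    def test_abutting_claims_merge_into_one_stay(self):
        med = _med([("2012-03-01", "2012-03-05", "IP", None, 100),
                    ("2012-03-05", "2012-03-09", "IP", None, 100)])
        assert roll_up_admissions(med) == 1

    def test_separate_claims_are_separate_stays(self):
        med = _med([("2012-03-01", "2012-03-03", "IP", None, 100),
                    ("2012-05-01", "2012-05-02", "IP", None, 100)])
        assert roll_up_admissions(med) == 2

    def test_stay_attributed_to_admission_window(self):
        # admitted on the last baseline day, discharged in follow-up
        med = _med([("2011-12-31", "2012-01-04", "IP", None, 100)])
        baseline = (pd.Timestamp("2011-01-01"), pd.Timestamp("2011-12-31"))
        followup = (pd.Timestamp("2012-01-01"), pd.Timestamp("2012-12-30"))
        assert roll_up_admissions(med, baseline) == 1
        assert roll_up_admissions(med, followup) == 0


class TestCountVisits:
    def test_same_day_ed_lines_count_once(self):
        med = _med([("2012-03-01", "2012-03-01", "ED", None, 100)] * 3)
        assert count_visits(med, "ED") == 1

    def test_same_day_claims_across_outpatient_settings_count_once(self):
        med = _med([("2012-03-01", "2012-03-01", "office", None, 100),
                    ("2012-03-01", "2012-03-01", "OP-hospital", None, 100)])
        assert count_visits(med, "outpatient") == 1

    def test_no_claims(self):
        assert count_visits(_EMPTY_MED, "ED") == 0


class TestSummarizeWindow:
    def test_single_office_claim(self, cpi_identity, maps):
        med = _med([("2012-03-01", "2012-03-01", "office", None, 200)])
        s = summarize_window(med, _EMPTY_RX, _W, cpi_identity, medication_hcpcs(maps))
        assert s["n_outpatient_visits"] == 1 and s["any_outpatient"]
        assert s["cost_outpatient"] == pytest.approx(200)
        assert s["cost_pharmacy"] == 0
        assert s["cost_combined"] == pytest.approx(200)

    def test_infusion_dollars_route_to_pharmacy_but_visit_counts(self, cpi_identity, maps):
        med = _med([("2012-03-01", "2012-03-01", "OP-hospital", "J1745", 3000)])
        s = summarize_window(med, _EMPTY_RX, _W, cpi_identity, medication_hcpcs(maps))
        assert s["n_outpatient_visits"] == 1
        assert s["cost_pharmacy"] == pytest.approx(3000)
        assert s["cost_outpatient"] == 0
        assert s["cost_total_medical"] == 0
        assert s["cost_combined"] == pytest.approx(3000)

    def test_other_setting_in_total_medical_only(self, cpi_identity, maps):
        med = _med([("2012-03-01", "2012-03-01", "other", None, 500),
                    ("2012-04-01", "2012-04-01", "office", None, 200)])
        s = summarize_window(med, _EMPTY_RX, _W, cpi_identity, medication_hcpcs(maps))
        assert s["cost_outpatient"] == pytest.approx(200)
        assert s["cost_total_medical"] == pytest.approx(700)

    def test_empty_window_all_zero(self, cpi_identity, maps):
        s = summarize_window(_EMPTY_MED, _EMPTY_RX, _W, cpi_identity, medication_hcpcs(maps))
        assert all(v == 0 for k, v in s.items() if k.startswith(("n_", "cost_")))
        assert not s["any_admission"]


class TestVectorizedParity:
    def test_summaries_match_per_window_computation(self, edge_run, edge_tables, maps):
        """Population rollup equals the scalar per-patient-window operation."""
        from ibd_claims.outcomes import CpiTable

        cpi = CpiTable.from_package()
        med_set = medication_hcpcs(maps)
        summaries = edge_run.summaries
        inc = edge_run.index_records[edge_run.index_records["included"]]
        sample = inc.sample(25, random_state=5)
        for row in sample.itertuples(index=False):
            idx = pd.Timestamp(row.index_date)
            med = edge_tables.medical[edge_tables.medical["person_id"] == row.person_id]
            rx = edge_tables.pharmacy[edge_tables.pharmacy["person_id"] == row.person_id]
            for wname, bounds in {
                "baseline": (idx - pd.Timedelta(days=365), idx - pd.Timedelta(days=1)),
                "follow-up": (idx, idx + pd.Timedelta(days=364)),
            }.items():
                expected = summarize_window(med, rx, bounds, cpi, med_set)
                got = summaries[(summaries["person_id"] == row.person_id)
                                & (summaries["window"] == wname)].iloc[0]
                for key, val in expected.items():
                    assert got[key] == pytest.approx(val), (row.person_id, wname, key)


class TestCostIdentities:
    def test_combined_equals_medical_plus_pharmacy(self, edge_run):
        s = edge_run.summaries
        assert np.allclose(s["cost_combined"],
                           s["cost_total_medical"] + s["cost_pharmacy"])

    def test_category_costs_bounded_by_total_medical(self, edge_run):
        s = edge_run.summaries
        named = s["cost_inpatient"] + s["cost_ed"] + s["cost_outpatient"]
        assert (named <= s["cost_total_medical"] + 1e-9).all()


class TestAggregate:
    @pytest.mark.parametrize("n,n_any,expected", [(616, 126, 20.46), (1489, 172, 11.55),
                                                  (1861, 613, 32.94)])
    def test_printed_any_proportions(self, n, n_any, expected):
        df = pd.DataFrame({
            "cohort": "UC", "drug": "adalimumab", "population": "as-treated",
            "window": "baseline",
            "person_id": [f"P{i}" for i in range(n)],
            "n_admissions": [1 if i < n_any else 0 for i in range(n)],
            "n_ed_visits": 0, "n_outpatient_visits": 0,
            "any_admission": [i < n_any for i in range(n)],
            "any_ed": False, "any_outpatient": False,
            "cost_inpatient": 0.0, "cost_ed": 0.0, "cost_outpatient": 0.0,
            "cost_total_medical": 0.0, "cost_pharmacy": 0.0, "cost_combined": 0.0,
        })
        out = aggregate(df)
        assert out.iloc[0]["any_admission_pct"] == expected
        assert out.iloc[0]["any_admission_n"] == n_any

    def test_identical_values_have_zero_sd(self):
        df = pd.DataFrame({
            "cohort": "UC", "drug": "x", "population": "ITT", "window": "baseline",
            "n_admissions": [2, 2, 2], "n_ed_visits": 0, "n_outpatient_visits": 0,
            "any_admission": True, "any_ed": False, "any_outpatient": False,
            "cost_inpatient": 100.0, "cost_ed": 0.0, "cost_outpatient": 0.0,
            "cost_total_medical": 100.0, "cost_pharmacy": 0.0, "cost_combined": 100.0,
        })
        out = aggregate(df)
        assert out.iloc[0]["n_admissions_sd"] == 0.0
        assert out.iloc[0]["cost_inpatient_mean"] == 100.0

    def test_sample_sd_uses_n_minus_one(self):
        df = pd.DataFrame({
            "cohort": "UC", "drug": "x", "population": "ITT", "window": "baseline",
            "n_admissions": [0, 2], "n_ed_visits": 0, "n_outpatient_visits": 0,
            "any_admission": [False, True], "any_ed": False, "any_outpatient": False,
            "cost_inpatient": 0.0, "cost_ed": 0.0, "cost_outpatient": 0.0,
            "cost_total_medical": 0.0, "cost_pharmacy": 0.0, "cost_combined": 0.0,
        })
        out = aggregate(df)
        assert out.iloc[0]["n_admissions_sd"] == pytest.approx(np.std([0, 2], ddof=1), abs=0.005)
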