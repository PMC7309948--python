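"""Synthetic MarketScan-like claims with known ground truth.

The generator emulates the structure of US commercial administrative claims
— multi-span enrollment with benefit flags, diagnosis-coded medical claims
across settings, pharmacy fills with NDC and days supply, per-claim paid
amounts — for a population of biologic initiators with ulcerative colitis
(UC) or Crohn's disease (CD). Every patient carries a ground-truth record
(true index date and drug, true discontinuation date, true cohort, expected
exclusion reason) so each downstream stage can be tested for parameter
recovery without proprietary data.

Generating model, per patient:

* index drug ~ ``market_shares``; index date uniform over the accrual window;
* time to discontinuation ~ Exponential with per-drug median (memoryless,
  single parameter, closed-form persistence fraction);
* biologic claims on a regular grid at the drug's maintenance dosing
  interval, via pharmacy fills (self-injected drugs, ``days_supply`` =
  interval) or facility administrations (infused drugs, HCPCS), ending at
  the true discontinuation time;
* utilization counts ~ Poisson with window-specific annual rates, on
  distinct service dates; per-claim paid amounts log-normal per category;
* a configurable fraction of patients receive one induced protocol defect
  (baseline enrollment gap, pre-index biologic, or cancer diagnosis) whose
  expected exclusion reason is recorded in the ground truth.

``expected_reason`` refers to the primary one-year design: patients whose
only defect is enrollment ending between 12 and 24 months after index are
``none`` here but drop out of the two-year cohort.
"""

from __future__ import annotations

import datetime as dt
import math
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .codemaps import BIOLOGICS, DrugCodeMap, load_drug_code_maps
from .config import AGE_BANDS, REGIONS, SimConfig

_DAY = dt.timedelta(days=1)
_UC_CODE = "556.9"
_CD_CODE = "555.9"
_CANCER_CODE = "153.9"
#: non-malignant comorbidity codes stamped on baseline visits (code, n.a.)
_COMORBIDITY_CODES = ("428.0", "493.90", "250.00", "571.5", "582.9")
_OP_SETTINGS = ("OP-clinic", "OP-hospital", "office")

ENROLLMENT_COLUMNS = [
    "person_id", "span_start", "span_end", "has_medical", "has_pharmacy",
    "birth_date", "sex", "region",
]
MEDICAL_COLUMNS = [
    "claim_id", "person_id", "service_start", "service_end", "setting",
    "dx1", "dx2", "dx3", "dx4", "hcpcs", "paid_usd", "service_year",
]
PHARMACY_COLUMNS = [
    "claim_id", "person_id", "fill_date", "ndc", "days_supply", "paid_usd",
    "service_year",
]
GROUND_TRUTH_COLUMNS = [
    "person_id", "disease", "cohort", "index_drug", "index_date",
    "discontinuation_date", "age_at_index", "expected_reason",
]

_DATE_COLS = {
    "enrollment": ["span_start", "span_end", "birth_date"],
    "medical": ["service_start", "service_end"],
    "pharmacy": ["fill_date"],
    "ground_truth": ["index_date", "discontinuation_date"],
}


class SimTables(NamedTuple):
    """The generated claim tables plus per-patient ground truth."""

    enrollment: pd.DataFrame
    medical: pd.DataFrame
    pharmacy: pd.DataFrame
    ground_truth: pd.DataFrame

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in self._fields:
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)

    @classmethod
    def read(cls, indir) -> "SimTables":
        from pathlib import Path

        indir = Path(indir)
        frames = {}
        for name in cls._fields:
            df = pd.read_csv(indir / f"{name}.csv")
            for col in _DATE_COLS[name]:
                if col in df.columns:
                    df[col] = pd.to_datetime(df[col])
            frames[name] = df
        return cls(**frames)


class _Emitter:
    """Accumulates claim rows with deterministic sequential claim ids."""

    def __init__(self) -> None:
        self.enrollment: list[dict] = []
        self.medical: list[dict] = []
        self.pharmacy: list[dict] = []
        self.truth: list[dict] = []
        self._mid = 0
        self._rid = 0

    def span(self, pid, start, end, *, birth, sex, region) -> None:
        self.enrollment.append(
            dict(person_id=pid, span_start=start, span_end=end, has_medical=True,
                 has_pharmacy=True, birth_date=birth, sex=sex, region=region)
        )

    def med(self, pid, start, setting, paid, *, end=None, dx1=None, dx2=None,
            dx3=None, dx4=None, hcpcs=None) -> None:
        self._mid += 1
        end = end or start
        self.medical.append(
            dict(claim_id=f"M{self._mid:08d}", person_id=pid, service_start=start,
                 service_end=end, setting=setting, dx1=dx1, dx2=dx2, dx3=dx3,
                 dx4=dx4, hcpcs=hcpcs, paid_usd=round(paid, 2),
                 service_year=start.year)
        )

    def rx(self, pid, date, ndc, days_supply, paid) -> None:
        self._rid += 1
        self.pharmacy.append(
            dict(claim_id=f"R{self._rid:08d}", person_id=pid, fill_date=date,
                 ndc=ndc, days_supply=int(days_supply), paid_usd=round(paid, 2),
                 service_year=date.year)
        )

    def to_tables(self) -> SimTables:
        enr = pd.DataFrame(self.enrollment, columns=ENROLLMENT_COLUMNS)
        med = pd.DataFrame(self.medical, columns=MEDICAL_COLUMNS)
        ph = pd.DataFrame(self.pharmacy, columns=PHARMACY_COLUMNS)
        gt = pd.DataFrame(self.truth, columns=GROUND_TRUTH_COLUMNS)
        for name, df in (("enrollment", enr), ("medical", med), ("pharmacy", ph),
                         ("ground_truth", gt)):
            for col in _DATE_COLS[name]:
                df[col] = pd.to_datetime(df[col])
        return SimTables(enr, med, ph, gt)


def _lognormal(rng: np.random.Generator, params) -> float:
    return float(np.exp(rng.normal(params.mu, params.sigma)))


def _distinct_dates(rng, start: dt.date, n_days: int, k: int) -> list[dt.date]:
    k = min(k, n_days)
    offs = rng.choice(n_days, size=k, replace=False)
    return [start + dt.timedelta(days=int(o)) for o in sorted(offs)]


def _emit_biologic_claim(em: _Emitter, rng, pid, date, drug_map: DrugCodeMap,
                         cohort_code: str, cost_params, k: int) -> None:
    paid = _lognormal(rng, cost_params)
    if drug_map.route == "pharmacy":
        em.rx(pid, date, sorted(drug_map.ndc_codes)[0], drug_map.dosing_interval_days, paid)
    elif drug_map.drug == "vedolizumab":
        # rotate through the three identification routes of the algorithm
        route = k % 3
        if route == 0:
            em.med(pid, date, "OP-hospital", paid, dx1=cohort_code, hcpcs="C9026")
        elif route == 1:
            em.med(pid, date, "OP-hospital", paid, dx1=cohort_code, hcpcs="J3380")
        else:
            em.med(pid, date, "OP-hospital", paid, dx1=cohort_code, hcpcs="J3590")
    else:
        em.med(pid, date, "OP-hospital", paid, dx1=cohort_code,
               hcpcs=sorted(drug_map.hcpcs_codes)[0])


def _in_gap(date: dt.date, gap: tuple[dt.date, dt.date] | None) -> bool:
    return gap is not None and gap[0] <= date <= gap[1]


def generate_population(
    config: SimConfig,
    maps: Mapping[str, DrugCodeMap] | None = None,
) -> SimTables:
    """Generate enrollment, medical and pharmacy tables plus ground truth.

    Deterministic for a fixed config (including seed): identical inputs
    produce identical tables. Every claim service date lies inside one of
    its patient's enrollment spans.
    """
    if maps is None:
        maps = load_drug_code_maps()
    rng = np.random.default_rng(config.seed)
    em = _Emitter()

    drugs = sorted(config.market_shares)
    drug_p = np.array([config.market_shares[d] for d in drugs])
    diseases = ("UC", "CD", "both")
    disease_p = np.array([config.disease_mix[d] for d in diseases])
    bands = list(AGE_BANDS)
    band_p = np.array([config.age_distribution[b] for b in bands])
    regions = list(REGIONS)
    region_p = np.array([config.region_probs[r] for r in regions])
    window_days = (config.study_end - config.study_start).days + 1
    ln2 = math.log(2.0)

    for i in range(config.n_patients):
        pid = f"P{i:06d}"

        # one induced protocol defect at most
        u = rng.random()
        if u < config.enrollment_gap_prob:
            defect = "enrollment"
        elif u < config.enrollment_gap_prob + config.baseline_biologic_prob:
            defect = "baseline-biologic"
        elif u < (config.enrollment_gap_prob + config.baseline_biologic_prob
                  + config.cancer_prob):
            defect = "cancer"
        else:
            defect = "none"

        disease = diseases[rng.choice(len(diseases), p=disease_p)]
        if disease == "both":
            cohort = "UC" if rng.random() < 0.5 else "CD"
        else:
            cohort = disease
        cohort_code = _UC_CODE if cohort == "UC" else _CD_CODE
        drug = drugs[rng.choice(len(drugs), p=drug_p)]
        dmap = maps[drug]

        if defect == "baseline-biologic":
            # index early in the window so the pre-index claim predates it
            index = config.study_start + dt.timedelta(days=int(rng.integers(0, 91)))
        else:
            index = config.study_start + dt.timedelta(days=int(rng.integers(0, window_days)))

        band = bands[rng.choice(len(bands), p=band_p)]
        lo, hi = (80, 89) if band == "80+" else tuple(int(x) for x in band.split("-"))
        age = int(rng.integers(lo, hi + 1))
        birth = index - dt.timedelta(days=round(age * 365.25) + int(rng.integers(10, 300)))
        sex = "F" if rng.random() < config.sex_female_prob else "M"
        region = regions[rng.choice(len(regions), p=region_p)]

        # enrollment
        pad_pre = int(rng.integers(30, 400))
        base_start = index - dt.timedelta(days=365 + pad_pre)
        gap: tuple[dt.date, dt.date] | None = None
        if defect == "enrollment":
            gap_start = index - dt.timedelta(days=200)
            gap_end = gap_start + dt.timedelta(days=int(rng.integers(10, 61)) - 1)
            gap = (gap_start, gap_end)
            span_end = index + dt.timedelta(days=730 + int(rng.integers(30, 400)))
            em.span(pid, base_start, gap_start - _DAY, birth=birth, sex=sex, region=region)
            em.span(pid, gap_end + _DAY, span_end, birth=birth, sex=sex, region=region)
        else:
            if rng.random() < config.two_year_coverage_prob:
                span_end = index + dt.timedelta(days=730 + int(rng.integers(30, 400)))
            else:
                span_end = index + dt.timedelta(days=365 + int(rng.integers(30, 330)))
            em.span(pid, base_start, span_end, birth=birth, sex=sex, region=region)

        # discontinuation and biologic claims
        median = config.discontinuation_median_days[drug]
        t_disc = int(math.floor(rng.exponential(scale=median / ln2)))
        disc_date = index + dt.timedelta(days=t_disc)
        horizon = min(t_disc, (span_end - index).days, 740)
        cost = config.biologic_claim_cost[drug]
        k = 0
        while k * dmap.dosing_interval_days <= horizon:
            date = index + dt.timedelta(days=k * dmap.dosing_interval_days)
            if not _in_gap(date, gap):
                _emit_biologic_claim(em, rng, pid, date, dmap, cohort_code, cost, k)
            k += 1
        if defect == "baseline-biologic":
            date = index - dt.timedelta(days=100)
            _emit_biologic_claim(em, rng, pid, date, dmap, cohort_code, cost, 0)

        # IBD diagnosis codes ride on the baseline outpatient visits so the
        # visit counts stay Poisson-faithful; 'both'-coded patients get
        # strictly unequal UC/CD visit-date counts
        if disease == "both":
            n_major = 2 + int(rng.poisson(1.0))
            n_minor = int(rng.integers(1, n_major))
        else:
            n_major = 1 + int(rng.poisson(2.0))
            n_minor = 0
        minor_code = _CD_CODE if cohort == "UC" else _UC_CODE
        comorbid_code = None
        if rng.random() < config.comorbidity_prob:
            comorbid_code = _COMORBIDITY_CODES[int(rng.integers(0, len(_COMORBIDITY_CODES)))]

        # window utilization: baseline at baseline rates, post-index at
        # follow-up rates over the full enrolled horizon
        followup_days = min((span_end - index).days + 1, 730)
        for wname, wstart, wdays in (
            ("baseline", index - dt.timedelta(days=365), 365),
            ("followup", index, followup_days),
        ):
            rates = config.utilization_rates[wname]
            frac = wdays / 365.0
            for _ in range(rng.poisson(rates.inpatient * frac)):
                admit = wstart + dt.timedelta(days=int(rng.integers(0, wdays)))
                los = 1 + int(rng.poisson(3.0))
                discharge = min(admit + dt.timedelta(days=los), span_end)
                if _in_gap(admit, gap):
                    continue
                em.med(pid, admit, "IP", _lognormal(rng, config.cost_params["inpatient_stay"]),
                       end=discharge, dx1=cohort_code)
            for date in _distinct_dates(rng, wstart, wdays, rng.poisson(rates.ed * frac)):
                if _in_gap(date, gap):
                    continue
                em.med(pid, date, "ED", _lognormal(rng, config.cost_params["ed_visit"]),
                       dx1=cohort_code)
            n_op = rng.poisson(rates.outpatient * frac)
            if wname == "baseline":
                n_op = max(n_op, n_major + n_minor)
                dx_codes = ([cohort_code] * n_major + [minor_code] * n_minor
                            + [None] * (n_op - n_major - n_minor))
                dx_codes = [dx_codes[j] for j in rng.permutation(n_op)]
            else:
                dx_codes = [None] * n_op
            for date, dx1 in zip(_distinct_dates(rng, wstart, wdays, n_op), dx_codes):
                if _in_gap(date, gap):
                    continue
                em.med(pid, date, _OP_SETTINGS[int(rng.integers(0, 3))],
                       _lognormal(rng, config.cost_params["outpatient_visit"]),
                       dx1=dx1, dx2=comorbid_code if dx1 is not None else None)
            for date in _distinct_dates(rng, wstart, wdays, rng.poisson(rates.other * frac)):
                if _in_gap(date, gap):
                    continue
                em.med(pid, date, "other", _lognormal(rng, config.cost_params["other_visit"]))
            # non-biologic pharmacy fills
            for date in _distinct_dates(rng, wstart, wdays,
                                        rng.poisson(config.rx_fills_per_year * frac)):
                if _in_gap(date, gap):
                    continue
                em.rx(pid, date, "99999999991", 30, _lognormal(rng, config.cost_params["rx_fill"]))

        if defect == "cancer":
            date = index + dt.timedelta(days=int(rng.integers(30, 301)))
            em.med(pid, date, "office",
                   _lognormal(rng, config.cost_params["outpatient_visit"]),
                   dx1=_CANCER_CODE)

        em.truth.append(
            dict(person_id=pid, disease=disease, cohort=cohort, index_drug=drug,
                 index_date=index, discontinuation_date=disc_date, age_at_index=age,
                 expected_reason=defect)
        )

    return em.to_tables()


def inject_edge_cases(
    tables: SimTables,
    maps: Mapping[str, DrugCodeMap] | None = None,
) -> SimTables:
    """Append deterministic hand-built patients exercising each exclusion rule.

    The appended patients cover: under-age at index, equal UC/CD visit
    counts (tie), a biologic claim inside the baseline washout, a cancer
    diagnosis during the study period, a baseline enrollment gap, a missing
    IBD diagnosis, two different drugs initiated on the same day
    (ambiguous index), and one clean includable control. Each carries its
    expected exclusion reason in the ground-truth table.
    """
    if maps is None:
        maps = load_drug_code_maps()
    em = _Emitter()
    # continue claim-id sequences past the generated ones
    em._mid = len(tables.medical)
    em._rid = len(tables.pharmacy)
    ada = maps["adalimumab"]
    inflix = maps["infliximab"]
    ada_ndc = sorted(ada.ndc_codes)[0]
    index = dt.date(2012, 6, 1)

    def enroll(pid, *, birth, start=None, end=None):
        em.span(pid, start or dt.date(2011, 1, 1), end or dt.date(2015, 6, 30),
                birth=birth, sex="F", region="South")

    def uc_visit(pid, date, code=_UC_CODE):
        em.med(pid, date, "office", 150.0, dx1=code)

    def ada_fills(pid, start, n):
        for k in range(n):
            em.rx(pid, start + dt.timedelta(days=14 * k), ada_ndc, 14, 1700.0)

    adult = dt.date(1980, 3, 15)

    # age: 17 years old at index
    pid = "EDGE_age"
    enroll(pid, birth=index - dt.timedelta(days=round(17 * 365.25) + 100))
    uc_visit(pid, dt.date(2012, 2, 1))
    ada_fills(pid, index, 27)
    em.truth.append(dict(person_id=pid, disease="UC", cohort="UC", index_drug="adalimumab",
                         index_date=index, discontinuation_date=dt.date(2013, 6, 1),
                         age_at_index=17, expected_reason="age"))

    # tie: equal numbers of UC- and CD-coded visit dates in baseline
    pid = "EDGE_tie"
    enroll(pid, birth=adult)
    uc_visit(pid, dt.date(2012, 1, 10), _UC_CODE)
    uc_visit(pid, dt.date(2012, 2, 10), _UC_CODE)
    uc_visit(pid, dt.date(2012, 3, 10), _CD_CODE)
    uc_visit(pid, dt.date(2012, 4, 10), _CD_CODE)
    ada_fills(pid, index, 27)
    em.truth.append(dict(person_id=pid, disease="both", cohort=None, index_drug="adalimumab",
                         index_date=index, discontinuation_date=dt.date(2013, 6, 1),
                         age_at_index=32, expected_reason="tie-excluded"))

    # baseline biologic: infliximab administration 100 days before index;
    # the prior claim must predate the accrual window or it would itself
    # become the index event, so this patient indexes early in the window
    pid = "EDGE_washout"
    wo_index = dt.date(2010, 6, 1)
    enroll(pid, birth=adult, start=dt.date(2009, 1, 1), end=dt.date(2013, 6, 30))
    uc_visit(pid, dt.date(2010, 2, 1))
    em.med(pid, wo_index - dt.timedelta(days=100), "OP-hospital", 6800.0,
           hcpcs=sorted(inflix.hcpcs_codes)[0])
    ada_fills(pid, wo_index, 27)
    em.truth.append(dict(person_id=pid, disease="UC", cohort="UC", index_drug="adalimumab",
                         index_date=wo_index, discontinuation_date=dt.date(2011, 6, 1),
                         age_at_index=30, expected_reason="baseline-biologic"))

    # cancer diagnosis during follow-up
    pid = "EDGE_cancer"
    enroll(pid, birth=adult)
    uc_visit(pid, dt.date(2012, 2, 1))
    em.med(pid, dt.date(2012, 9, 1), "office", 220.0, dx1=_CANCER_CODE)
    ada_fills(pid, index, 27)
    em.truth.append(dict(person_id=pid, disease="UC", cohort="UC", index_drug="adalimumab",
                         index_date=index, discontinuation_date=dt.date(2013, 6, 1),
                         age_at_index=32, expected_reason="cancer"))

    # enrollment gap inside baseline
    pid = "EDGE_gap"
    em.span(pid, dt.date(2011, 1, 1), dt.date(2011, 12, 1), birth=adult, sex="F",
            region="South")
    em.span(pid, dt.date(2012, 1, 15), dt.date(2015, 6, 30), birth=adult, sex="F",
            region="South")
    uc_visit(pid, dt.date(2012, 2, 1))
    ada_fills(pid, index, 27)
    em.truth.append(dict(person_id=pid, disease="UC", cohort="UC", index_drug="adalimumab",
                         index_date=index, discontinuation_date=dt.date(2013, 6, 1),
                         age_at_index=32, expected_reason="enrollment"))

    # no IBD diagnosis anywhere in baseline
    pid = "EDGE_nodx"
    enroll(pid, birth=adult)
    em.med(pid, dt.date(2012, 2, 1), "office", 150.0, dx1="714.0")
    ada_fills(pid, index, 27)
    em.truth.append(dict(person_id=pid, disease=None, cohort=None, index_drug="adalimumab",
                         index_date=index, discontinuation_date=dt.date(2013, 6, 1),
                         age_at_index=32, expected_reason="no-IBD-dx"))

    # two different biologics on the same first day
    pid = "EDGE_ambig"
    enroll(pid, birth=adult)
    uc_visit(pid, dt.date(2012, 2, 1))
    em.rx(pid, index, ada_ndc, 14, 1700.0)
    em.med(pid, index, "OP-hospital", 6800.0, hcpcs=sorted(inflix.hcpcs_codes)[0])
    em.truth.append(dict(person_id=pid, disease="UC", cohort="UC", index_drug=None,
                         index_date=index, discontinuation_date=index,
                         age_at_index=32, expected_reason="ambiguous-index"))

    # clean includable control
    pid = "EDGE_ok"
    enroll(pid, birth=adult)
    uc_visit(pid, dt.date(2012, 2, 1))
    ada_fills(pid, index, 27)
    em.truth.append(dict(person_id=pid, disease="UC", cohort="UC", index_drug="adalimumab",
                         index_date=index, discontinuation_date=dt.date(2013, 6, 1),
                         age_at_index=32, expected_reason="none"))

    extra = em.to_tables()
    return SimTables(
        enrollment=pd.concat([tables.enrollment, extra.enrollment], ignore_index=True),
        medical=pd.concat([tables.medical, extra.medical], ignore_index=True),
        pharmacy=pd.concat([tables.pharmacy, extra.pharmacy], ignore_index=True),
        ground_truth=pd.concat([tables.ground_truth, extra.ground_truth], ignore_index=True),
    )


EDGE_CASE_IDS: tuple[str, ...] = (
    "EDGE_age", "EDGE_tie", "EDGE_washout", "EDGE_cancer", "EDGE_gap",
    "EDGE_nodx", "EDGE_ambig", "EDGE_ok",
)
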