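"""New-user cohort construction: index selection and the eligibility cascade.

The index date is the first qualifying biologic claim inside the accrual
window. Eligibility is then applied in a fixed order, each stage recording
its exclusions in an attrition log:

1. unambiguous index drug (two different drugs on the earliest date exclude
   the patient),
2. age >= 18 years at index,
3. continuous enrollment with medical and pharmacy benefits over
   ``[index - baseline_days, index + followup_days - 1]``,
4. at least one UC (ICD-9-CM 556.xx) or CD (555.xx) diagnosis during
   baseline or on the index date, with cohort assignment by the larger
   count of diagnosis-coded visit dates (equal nonzero counts excluded),
5. washout: no biologic claim of any kind in ``[index - baseline_days,
   index - 1]`` (new-user requirement; the index-day claim itself does not
   trigger it),
6. no cancer diagnosis (ICD-9-CM 140-208) from baseline start through
   follow-up end.

All windows are closed intervals in whole days; baseline is
``[index - baseline_days, index - 1]`` and follow-up ``[index,
index + followup_days - 1]`` — index-day claims belong to follow-up.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .codemaps import CD_DX_PREFIX, UC_DX_PREFIX, charlson_score, load_charlson_map
from .config import StudyConfig

DX_COLUMNS = ["dx1", "dx2", "dx3", "dx4"]

EXCLUSION_STAGES: tuple[str, ...] = (
    "ambiguous-index",
    "age",
    "enrollment",
    "no-IBD-dx",
    "tie-excluded",
    "baseline-biologic",
    "cancer",
)

INDEX_RECORD_COLUMNS = [
    "person_id", "index_date", "index_drug", "cohort", "age_at_index", "sex",
    "region", "charlson", "index_year", "included", "exclusion_reason",
]


def age_years(birth_date, on_date) -> int:
    """Completed years of age, whole-day arithmetic."""
    return int((pd.Timestamp(on_date) - pd.Timestamp(birth_date)).days // 365.25)


def merge_spans(spans: Iterable[tuple]) -> list[tuple]:
    """Merge overlapping or abutting (gap of zero days) date intervals."""
    spans = sorted((pd.Timestamp(a), pd.Timestamp(b)) for a, b in spans)
    merged: list[list] = []
    for a, b in spans:
        if merged and a <= merged[-1][1] + pd.Timedelta(days=1):
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(m) for m in merged]


def check_enrollment(spans: pd.DataFrame, index_date, baseline_days: int,
                     followup_days: int) -> bool:
    """True iff spans with both benefits cover every day of the study window.

    The window is ``[index - baseline_days, index + followup_days - 1]``,
    closed, with zero-day tolerance; abutting spans count as continuous.
    """
    if len(spans) == 0:
        return False
    if "has_medical" in spans.columns:
        spans = spans[spans["has_medical"].astype(bool) & spans["has_pharmacy"].astype(bool)]
    index_date = pd.Timestamp(index_date)
    lo = index_date - pd.Timedelta(days=baseline_days)
    hi = index_date + pd.Timedelta(days=followup_days - 1)
    for a, b in merge_spans(zip(spans["span_start"], spans["span_end"])):
        if a <= lo and b >= hi:
            return True
    return False


def select_index(events: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Earliest in-window biologic event per person.

    Returns columns person_id, index_date, index_drug, ambiguous. Persons
    with no event inside the accrual window are absent; persons whose
    earliest date carries two different drugs get ``ambiguous=True`` and a
    null index_drug.
    """
    ws = pd.Timestamp(config.index_window_start)
    we = pd.Timestamp(config.index_window_end)
    inw = events[(events["event_date"] >= ws) & (events["event_date"] <= we)]
    if len(inw) == 0:
        return pd.DataFrame(columns=["person_id", "index_date", "index_drug", "ambiguous"])
    first_date = inw.groupby("person_id")["event_date"].min()
    at_first = inw.merge(first_date.rename("index_date"), left_on="person_id",
                         right_index=True)
    at_first = at_first[at_first["event_date"] == at_first["index_date"]]
    agg = at_first.groupby("person_id").agg(
        index_date=("index_date", "first"), n_drugs=("drug", "nunique"),
        index_drug=("drug", "first"),
    )
    agg["ambiguous"] = agg["n_drugs"] > 1
    agg.loc[agg["ambiguous"], "index_drug"] = None
    return agg.reset_index()[["person_id", "index_date", "index_drug", "ambiguous"]]


def assign_cohort(baseline_medical: pd.DataFrame) -> str:
    """Assign UC/CD from diagnosis-coded visit dates in one patient's baseline.

    Counts distinct service dates carrying a 556.xx (UC) code and distinct
    dates carrying a 555.xx (CD) code across all settings and diagnosis
    positions; the strictly larger count wins. Returns ``"UC"``, ``"CD"``,
    ``"tie"`` (equal nonzero counts) or ``"none"`` (no IBD diagnosis).
    """
    n_uc, n_cd = _count_dx_visit_dates(baseline_medical)
    if n_uc == 0 and n_cd == 0:
        return "none"
    if n_uc == n_cd:
        return "tie"
    return "UC" if n_uc > n_cd else "CD"


def _count_dx_visit_dates(med: pd.DataFrame) -> tuple[int, int]:
    if len(med) == 0:
        return 0, 0
    uc_dates: set = set()
    cd_dates: set = set()
    for col in DX_COLUMNS:
        if col not in med.columns:
            continue
        vals = med[col].astype("string").fillna("")
        uc_dates.update(med.loc[vals.str.startswith(UC_DX_PREFIX), "service_start"])
        cd_dates.update(med.loc[vals.str.startswith(CD_DX_PREFIX), "service_start"])
    return len(uc_dates), len(cd_dates)


def _any_dx_prefix(med: pd.DataFrame, prefixes: tuple[str, ...]) -> bool:
    for col in DX_COLUMNS:
        if col not in med.columns:
            continue
        vals = med[col].astype("string").fillna("")
        if vals.str.startswith(prefixes).any():
            return True
    return False


def build_cohort(
    tables,
    events: pd.DataFrame,
    config: StudyConfig,
    charlson_map=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the eligibility cascade; return (index records, attrition log).

    ``tables`` is a ``SimTables``-like bundle (enrollment/medical/pharmacy
    frames); ``events`` the classified biologic events. The attrition log
    has one row per stage with entering/excluded/passing counts; each
    excluded patient carries the reason of the first stage it failed.
    Vectorized over the whole population; semantically equivalent to
    applying :func:`check_enrollment` / :func:`assign_cohort` per patient.
    """
    for name in ("enrollment", "medical", "pharmacy"):
        df = getattr(tables, name)
        if not isinstance(df, pd.DataFrame):
            raise TypeError(f"tables.{name} must be a DataFrame")
    if charlson_map is None:
        charlson_map = load_charlson_map()
    bdays = config.baseline_days
    fdays = config.followup_days

    cand = select_index(events, config)
    if len(cand) == 0:
        empty = pd.DataFrame(columns=INDEX_RECORD_COLUMNS)
        return empty, _attrition_log(empty)
    pids = cand["person_id"]

    demo = tables.enrollment.drop_duplicates("person_id").set_index("person_id")
    birth = pids.map(demo["birth_date"])
    cand = cand.assign(
        sex=pids.map(demo["sex"]).to_numpy(),
        region=pids.map(demo["region"]).to_numpy(),
        age_at_index=((pd.to_datetime(cand["index_date"]) - pd.to_datetime(birth.to_numpy()))
                      .dt.days // 365.25).astype("Int64"),
    )

    # continuous both-benefit enrollment over [index-bdays, index+fdays-1]
    enr = tables.enrollment
    both = enr[enr["has_medical"].astype(bool) & enr["has_pharmacy"].astype(bool)]
    merged_spans = {
        pid: merge_spans(zip(g["span_start"], g["span_end"]))
        for pid, g in both.groupby("person_id")
    }
    idx_by_pid = dict(zip(cand["person_id"], pd.to_datetime(cand["index_date"])))
    enrolled = {}
    for pid, index in idx_by_pid.items():
        lo = index - pd.Timedelta(days=bdays)
        hi = index + pd.Timedelta(days=fdays - 1)
        enrolled[pid] = any(a <= lo and b >= hi for a, b in merged_spans.get(pid, ()))

    # claim-level masks relative to each candidate's index date
    med = tables.medical.merge(cand[["person_id", "index_date"]], on="person_id")
    rel = (med["service_start"] - med["index_date"]).dt.days
    uc_any = pd.Series(False, index=med.index)
    cd_any = pd.Series(False, index=med.index)
    cancer_any = pd.Series(False, index=med.index)
    for col in DX_COLUMNS:
        if col not in med.columns:
            continue
        vals = med[col].astype("string").fillna("")
        uc_any |= vals.str.startswith(UC_DX_PREFIX)
        cd_any |= vals.str.startswith(CD_DX_PREFIX)
        cancer_any |= vals.str.startswith(tuple(config.cancer_dx_prefixes))

    base_or_index = (rel >= -bdays) & (rel <= 0)
    n_uc = (med.loc[base_or_index & uc_any].groupby("person_id")["service_start"]
            .nunique().reindex(pids, fill_value=0).to_numpy())
    n_cd = (med.loc[base_or_index & cd_any].groupby("person_id")["service_start"]
            .nunique().reindex(pids, fill_value=0).to_numpy())
    in_study = (rel >= -bdays) & (rel <= fdays - 1)
    has_cancer = (med.loc[in_study & cancer_any].groupby("person_id").size()
                  .reindex(pids, fill_value=0).to_numpy() > 0)

    ev = events.merge(cand[["person_id", "index_date"]], on="person_id")
    relv = (ev["event_date"] - ev["index_date"]).dt.days
    has_washout = (ev.loc[(relv >= -bdays) & (relv < 0)].groupby("person_id").size()
                   .reindex(pids, fill_value=0).to_numpy() > 0)

    age = cand["age_at_index"].to_numpy(dtype=float)
    fails = [
        ("ambiguous-index", cand["ambiguous"].to_numpy(dtype=bool)),
        ("age", np.isnan(age) | (age < config.min_age)),
        ("enrollment", ~pids.map(enrolled).to_numpy(dtype=bool)),
        ("no-IBD-dx", (n_uc == 0) & (n_cd == 0)),
        ("tie-excluded", (n_uc == n_cd) & (n_uc > 0)),
        ("baseline-biologic", has_washout),
        ("cancer", has_cancer),
    ]
    reason = np.select([m for _, m in fails], [s for s, _ in fails], default="none")
    included = reason == "none"
    past_dx_stage = ~np.isin(reason, ("ambiguous-index", "age", "enrollment",
                                      "no-IBD-dx", "tie-excluded"))
    cohort = np.where(past_dx_stage, np.where(n_uc > n_cd, "UC", "CD"), None)

    # Charlson from strictly-baseline diagnoses, included patients only
    strict_base = med.loc[(rel >= -bdays) & (rel <= -1)]
    scores = pd.Series(0, index=pd.Index(pids, name="person_id"))
    if len(strict_base):
        dx_long = strict_base.melt(id_vars=["person_id"], value_vars=DX_COLUMNS,
                                   value_name="code")[["person_id", "code"]].dropna()
        dx_long["code"] = dx_long["code"].astype(str)
        for cat in charlson_map:
            hit = set(dx_long.loc[dx_long["code"].str.startswith(cat.prefixes), "person_id"])
            if hit:
                scores.loc[scores.index.isin(hit)] += cat.weight
    charlson = scores.to_numpy()

    index_records = pd.DataFrame({
        "person_id": pids.to_numpy(),
        "index_date": pd.to_datetime(cand["index_date"]).to_numpy(),
        "index_drug": cand["index_drug"].to_numpy(),
        "cohort": cohort,
        "age_at_index": cand["age_at_index"].to_numpy(),
        "sex": cand["sex"].to_numpy(),
        "region": cand["region"].to_numpy(),
        "charlson": np.where(included, charlson, None),
        "index_year": pd.to_datetime(cand["index_date"]).dt.year.to_numpy(),
        "included": included,
        "exclusion_reason": reason,
    }, columns=INDEX_RECORD_COLUMNS)
    attrition = _attrition_log(index_records)
    return index_records, attrition


def _attrition_log(index_records: pd.DataFrame) -> pd.DataFrame:
    entering = len(index_records)
    rows = [dict(stage="candidates (in-window biologic initiation)",
                 entering=entering, excluded=0, passing=entering)]
    n = entering
    for stage in EXCLUSION_STAGES:
        excluded = int((index_records["exclusion_reason"] == stage).sum()) if entering else 0
        rows.append(dict(stage=stage, entering=n, excluded=excluded, passing=n - excluded))
        n -= excluded
    rows.append(dict(stage="included", entering=n, excluded=0, passing=n))
    return pd.DataFrame(rows, columns=["stage", "entering", "excluded", "passing"])
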