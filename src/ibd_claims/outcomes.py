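"""Per-patient utilization and cost rollups for baseline and follow-up windows.

Utilization: inpatient claims are merged into stays when their date ranges
overlap or abut, and a stay is attributed to the window containing its
admission date; ED and outpatient visits are distinct service dates in
their setting class (outpatient = clinic, outpatient hospital, physician
office). Costs are per-claim paid amounts restated to US$2015 with the
Medical Care Component of the Consumer Price Index and attributed to the
window containing the claim's service start (pharmacy: fill date).

Cost categories: dollars on drug-administration medical claims (HCPCS in
the medication set) are routed to pharmacy cost together with pharmacy
fills — the visit still counts as utilization but its dollars are not
double-counted in the setting categories. Total medical cost covers all
non-medication medical claims in every setting, so it exceeds the sum of
the three named categories by the "other setting" remainder, and
``cost_combined = cost_total_medical + cost_pharmacy`` holds exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .util import pct, round_half_up

log = logging.getLogger(__name__)

OUTPATIENT_SETTINGS = ("OP-clinic", "OP-hospital", "office")

COUNT_FIELDS = ("n_admissions", "n_ed_visits", "n_outpatient_visits")
FLAG_FIELDS = ("any_admission", "any_ed", "any_outpatient")
COST_FIELDS = (
    "cost_inpatient", "cost_ed", "cost_outpatient", "cost_total_medical",
    "cost_pharmacy", "cost_combined",
)


@dataclass(frozen=True)
class CpiTable:
    """Calendar year -> inflation factor restating that year's US$ to US$2015."""

    factors: Mapping[int, float]

    def __post_init__(self) -> None:
        for year, f in self.factors.items():
            if f <= 0:
                raise ValueError(f"CPI factor for {year} must be > 0")

    @classmethod
    def from_package(cls) -> "CpiTable":
        with resources.files("ibd_claims.data").joinpath("cpi_medical.yaml").open() as fh:
            idx = {int(k): float(v) for k, v in yaml.safe_load(fh).items()}
        base = idx[2015]
        return cls(factors={y: base / v for y, v in idx.items()})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CpiTable":
        idx = {int(k): float(v) for k, v in yaml.safe_load(Path(path).read_text()).items()}
        base = idx[2015]
        return cls(factors={y: base / v for y, v in idx.items()})

    @classmethod
    def identity(cls, years: Iterable[int] = range(2000, 2031)) -> "CpiTable":
        return cls(factors={y: 1.0 for y in years})

    def factor(self, year: int) -> float:
        try:
            return self.factors[int(year)]
        except KeyError:
            raise KeyError(f"no CPI factor for service year {year}") from None


def adjust_cost(amount: float, service_year: int, cpi: CpiTable) -> float:
    """Restate a nominal amount from its service year to US$2015."""
    return amount * cpi.factor(service_year)


def merge_stays(ip_claims: pd.DataFrame) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Merge inpatient claims into stays (overlapping or abutting ranges)."""
    spans = sorted(
        (pd.Timestamp(a), pd.Timestamp(b))
        for a, b in zip(ip_claims["service_start"], ip_claims["service_end"])
    )
    merged: list[list] = []
    for a, b in spans:
        if merged and a <= merged[-1][1] + pd.Timedelta(days=1):
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(m) for m in merged]


def roll_up_admissions(ip_claims: pd.DataFrame, window: tuple | None = None) -> int:
    """Count inpatient stays, attributed by admission date.

    A stay admitted on the last baseline day but discharged during
    follow-up belongs to baseline only.
    """
    stays = merge_stays(ip_claims)
    if window is None:
        return len(stays)
    lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    return sum(1 for a, _ in stays if lo <= a <= hi)


def count_visits(claims: pd.DataFrame, setting_class: str) -> int:
    """Distinct service dates in a setting class (``"ED"`` or ``"outpatient"``)."""
    settings = ("ED",) if setting_class == "ED" else OUTPATIENT_SETTINGS
    sel = claims[claims["setting"].isin(settings)]
    return int(sel["service_start"].nunique())


def summarize_window(
    medical: pd.DataFrame,
    pharmacy: pd.DataFrame,
    window: tuple,
    cpi: CpiTable,
    med_hcpcs: frozenset[str],
) -> dict:
    """One patient's utilization counts and US$2015 costs for one window.

    ``medical`` should contain the patient's full medical claims so that
    inpatient stays spanning the window boundary merge correctly; all other
    quantities use claims whose service start (fill date) lies in the
    closed window.
    """
    lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    med_w = medical[(medical["service_start"] >= lo) & (medical["service_start"] <= hi)]
    ph_w = pharmacy[(pharmacy["fill_date"] >= lo) & (pharmacy["fill_date"] <= hi)]

    hc = med_w["hcpcs"].astype("string").fillna("")
    admin = hc.isin(med_hcpcs)
    adj = med_w["paid_usd"].to_numpy(dtype=float) * np.array(
        [cpi.factor(y) for y in med_w["service_year"]]
    ) if len(med_w) else np.array([])
    adj = pd.Series(adj, index=med_w.index)
    ph_adj = ph_w["paid_usd"].to_numpy(dtype=float) * np.array(
        [cpi.factor(y) for y in ph_w["service_year"]]
    ) if len(ph_w) else np.array([])

    ip_all = medical[medical["setting"] == "IP"]
    n_adm = roll_up_admissions(ip_all, (lo, hi))
    n_ed = count_visits(med_w, "ED")
    n_op = count_visits(med_w, "outpatient")

    svc = med_w[~admin]
    svc_adj = adj[~admin]
    by_setting = svc_adj.groupby(svc["setting"]).sum() if len(svc) else pd.Series(dtype=float)
    cost_ip = float(by_setting.get("IP", 0.0))
    cost_ed = float(by_setting.get("ED", 0.0))
    cost_op = float(sum(by_setting.get(s, 0.0) for s in OUTPATIENT_SETTINGS))
    cost_med = float(svc_adj.sum())
    cost_rx = float(np.sum(ph_adj)) + float(adj[admin].sum())

    return dict(
        n_admissions=n_adm, n_ed_visits=n_ed, n_outpatient_visits=n_op,
        any_admission=n_adm > 0, any_ed=n_ed > 0, any_outpatient=n_op > 0,
        cost_inpatient=cost_ip, cost_ed=cost_ed, cost_outpatient=cost_op,
        cost_total_medical=cost_med, cost_pharmacy=cost_rx,
        cost_combined=cost_med + cost_rx,
    )


def summarize_patients(
    tables,
    index_records: pd.DataFrame,
    followup_days: int,
    cpi: CpiTable,
    med_hcpcs: frozenset[str],
) -> pd.DataFrame:
    """Baseline and follow-up window summaries for every included patient.

    Baseline is ``[index-365, index-1]`` and follow-up ``[index,
    index+followup_days-1]``; the index-day claims (including the
    initiating biologic claim) belong to follow-up.
    """
    included = index_records[index_records["included"]]
    pids = included["person_id"]
    mi = pd.MultiIndex.from_product([pids, ["baseline", "follow-up"]],
                                    names=["person_id", "window"])
    out = pd.DataFrame(0.0, index=mi, columns=[*COUNT_FIELDS, *COST_FIELDS])
    if len(included) == 0:
        return out.reset_index().assign(
            **{f: False for f in FLAG_FIELDS}
        )[["person_id", "window", *COUNT_FIELDS, *FLAG_FIELDS, *COST_FIELDS]]
    key = included[["person_id", "index_date"]]

    def _windowed(df: pd.DataFrame, date_col: str) -> pd.DataFrame:
        df = df.merge(key, on="person_id")
        rel = (df[date_col] - df["index_date"]).dt.days
        window = np.select(
            [(rel >= -365) & (rel <= -1), (rel >= 0) & (rel <= followup_days - 1)],
            ["baseline", "follow-up"], default="",
        )
        df = df.assign(window=window)
        return df[df["window"] != ""]

    def _adjusted(df: pd.DataFrame) -> pd.Series:
        factors = df["service_year"].map(cpi.factors)
        if factors.isna().any():
            missing = sorted(df.loc[factors.isna(), "service_year"].unique())
            raise KeyError(f"no CPI factor for service year(s) {missing}")
        return df["paid_usd"].astype(float) * factors

    med = _windowed(tables.medical, "service_start")
    med = med.assign(_adj=_adjusted(med) if len(med) else [])
    admin = med["hcpcs"].astype("string").fillna("").isin(med_hcpcs)

    grp = ["person_id", "window"]
    ed = med[med["setting"] == "ED"].groupby(grp)["service_start"].nunique()
    op = med[med["setting"].isin(OUTPATIENT_SETTINGS)].groupby(grp)["service_start"].nunique()
    out["n_ed_visits"] = ed.reindex(mi, fill_value=0)
    out["n_outpatient_visits"] = op.reindex(mi, fill_value=0)

    # inpatient stays: merge each person's IP claims, attribute by admit date
    ip = tables.medical[tables.medical["setting"] == "IP"].merge(key, on="person_id")
    adm_counts: dict[tuple, int] = {}
    for pid, g in ip.groupby("person_id"):
        index = pd.Timestamp(g["index_date"].iloc[0])
        for a, _ in merge_stays(g):
            d = (a - index).days
            if -365 <= d <= -1:
                k = (pid, "baseline")
            elif 0 <= d <= followup_days - 1:
                k = (pid, "follow-up")
            else:
                continue
            adm_counts[k] = adm_counts.get(k, 0) + 1
    if adm_counts:
        s = pd.Series(adm_counts)
        s.index.names = ["person_id", "window"]
        out["n_admissions"] = s.reindex(mi, fill_value=0)

    svc = med[~admin]
    by_setting = svc.groupby(grp + ["setting"])["_adj"].sum().unstack(fill_value=0.0)
    by_setting = by_setting.reindex(mi, fill_value=0.0)
    for s in ("IP", "ED", *OUTPATIENT_SETTINGS, "other"):
        if s not in by_setting.columns:
            by_setting[s] = 0.0
    out["cost_inpatient"] = by_setting["IP"]
    out["cost_ed"] = by_setting["ED"]
    out["cost_outpatient"] = by_setting[list(OUTPATIENT_SETTINGS)].sum(axis=1)
    out["cost_total_medical"] = svc.groupby(grp)["_adj"].sum().reindex(mi, fill_value=0.0)

    ph = _windowed(tables.pharmacy, "fill_date")
    ph = ph.assign(_adj=_adjusted(ph) if len(ph) else [])
    rx = ph.groupby(grp)["_adj"].sum().reindex(mi, fill_value=0.0)
    rx = rx + med[admin].groupby(grp)["_adj"].sum().reindex(mi, fill_value=0.0)
    out["cost_pharmacy"] = rx
    out["cost_combined"] = out["cost_total_medical"] + out["cost_pharmacy"]

    out = out.reset_index()
    for c in COUNT_FIELDS:
        out[c] = out[c].astype(int)
    for flag, count in zip(FLAG_FIELDS, COUNT_FIELDS):
        out[flag] = out[count] > 0
    return out[["person_id", "window", *COUNT_FIELDS, *FLAG_FIELDS, *COST_FIELDS]]


def aggregate(
    summaries: pd.DataFrame,
    group_cols: Iterable[str] = ("cohort", "drug", "population", "window"),
) -> pd.DataFrame:
    """Group-level n, proportion-with-any and mean (SD) rows.

    Proportions are ``100 * count(any)/n`` rounded half-up to two decimals
    (126 of 616 prints as 20.46); means and sample SDs (n-1 denominator) to
    two decimals. Empty groups are omitted with a log entry.
    """
    group_cols = [c for c in group_cols if c in summaries.columns]
    rows = []
    for key, grp in summaries.groupby(group_cols, dropna=False, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n = len(grp)
        if n == 0:
            log.info("omitting empty group %s", key)
            continue
        out = dict(zip(group_cols, key)) | {"n": n}
        for flag, count in zip(FLAG_FIELDS, COUNT_FIELDS):
            n_any = int(grp[flag].sum())
            out[f"{flag}_n"] = n_any
            out[f"{flag}_pct"] = pct(n_any, n, 2)
        for field in (*COUNT_FIELDS, *COST_FIELDS):
            vals = grp[field].to_numpy(dtype=float)
            out[f"{field}_mean"] = round_half_up(float(np.mean(vals)), 2)
            sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
            out[f"{field}_sd"] = round_half_up(sd, 2)
        rows.append(out)
    return pd.DataFrame(rows)
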