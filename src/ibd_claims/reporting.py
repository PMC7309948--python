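"""Publication-style deliverables: characteristics, utilization/cost tables,
initiation shares, persistence and time-on-therapy tables, attrition.

All tables are plain DataFrames written as deterministic UTF-8 CSV; every
percentage is rounded half-up to the precision of the corresponding printed
table (characteristics and utilization proportions to two decimals,
initiation shares and persistence proportions to one).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .config import AGE_BANDS, REGIONS
from .episodes import persistence_summary
from .util import pct

CHARLSON_BANDS = ("0", "1", "2", "3", ">=4")

#: tables a complete report bundle must contain
REQUIRED_TABLES = (
    "characteristics",
    "utilization_costs",
    "initiation_shares",
    "persistence",
    "time_on_therapy",
    "attrition",
)


def _charlson_band(score) -> str:
    s = int(score)
    return ">=4" if s >= 4 else str(s)


def characteristics_table(index_records: pd.DataFrame) -> pd.DataFrame:
    """Cohort characteristics: n (%) by age band, sex, region, Charlson band
    and index year, per disease cohort, for the included population.

    Percentages are of the cohort N, rounded half-up to two decimals
    (1036 of 4864 prints as 21.30). An empty cohort yields zero counts.
    """
    inc = index_records[index_records["included"]]
    rows = []
    cohorts = sorted(inc["cohort"].dropna().unique()) or ["UC", "CD"]
    for cohort in cohorts:
        sub = inc[inc["cohort"] == cohort]
        n = len(sub)
        rows.append(dict(cohort=cohort, block="N", level="", n=n, pct=100.0 if n else 0.0))

        def block(name: str, levels, values) -> None:
            counts = values.value_counts()
            for lev in levels:
                c = int(counts.get(lev, 0))
                rows.append(dict(cohort=cohort, block=name, level=str(lev), n=c,
                                 pct=pct(c, n, 2) if n else 0.0))

        ages = sub["age_at_index"].map(_age_band)
        block("Age, years", AGE_BANDS, ages)
        block("Sex", ("Female", "Male"), sub["sex"].map({"F": "Female", "M": "Male"}))
        block("Region", REGIONS, sub["region"])
        block("Charlson score", CHARLSON_BANDS, sub["charlson"].map(_charlson_band))
        years = sorted(sub["index_year"].unique()) if n else []
        block("Index date", years, sub["index_year"])
    out = pd.DataFrame(rows, columns=["cohort", "block", "level", "n", "pct"])
    out["cell"] = out.apply(lambda r: f"{r['n']} ({r['pct']:.2f})", axis=1)
    return out


def _age_band(age) -> str:
    a = int(age)
    if a >= 80:
        return "80+"
    for band in AGE_BANDS[:-1]:
        lo, hi = (int(x) for x in band.split("-"))
        if lo <= a <= hi:
            return band
    return "<18"


def initiation_shares(index_records: pd.DataFrame) -> pd.DataFrame:
    """Per-cohort drug initiation counts and percentage shares (one decimal)."""
    inc = index_records[index_records["included"]]
    rows = []
    for cohort, sub in inc.groupby("cohort", sort=True):
        n = len(sub)
        for drug, c in sub["index_drug"].value_counts().sort_index().items():
            rows.append(dict(cohort=cohort, drug=drug, n=int(c), pct=pct(int(c), n, 1)))
    return pd.DataFrame(rows, columns=["cohort", "drug", "n", "pct"])


def build_bundle(
    index_records: pd.DataFrame,
    episodes: pd.DataFrame,
    utilization_costs: pd.DataFrame,
    attrition: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Assemble the six report tables from upstream pipeline outputs."""
    persist = persistence_summary(episodes)
    return {
        "characteristics": characteristics_table(index_records),
        "utilization_costs": utilization_costs,
        "initiation_shares": initiation_shares(index_records),
        "persistence": persist[["cohort", "drug", "n_initiators", "n_as_treated",
                                "pct_as_treated"]],
        "time_on_therapy": persist[["cohort", "drug", "n_initiators", "tot_q1",
                                    "tot_median", "tot_q3"]],
        "attrition": attrition,
    }


def render_bundle(bundle: Mapping[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """Write every bundle table as CSV; rerunning on identical inputs is
    byte-identical. Raises ``ValueError`` listing any missing table."""
    missing = [t for t in REQUIRED_TABLES if t not in bundle or bundle[t] is None]
    if missing:
        raise ValueError(f"report bundle missing tables: {missing}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(bundle):
        path = out / f"{name}.csv"
        bundle[name].to_csv(path, index=False)
        written.append(path)
    return written
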