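#!/usr/bin/env python
"""Windowed utilization and US$2015 cost rollups (utilization-table analogs).

Summarizes each included patient's baseline and follow-up windows
(admissions, ED visits, outpatient visits; category costs with
drug-administration dollars routed to pharmacy cost), inflates to US$2015
with the medical-care CPI, and aggregates to cohort x drug x population
(as-treated / ITT) x window means, SDs and proportions. Writes
results/utilization/ and prints the headline baseline-to-follow-up shifts.
"""

import argparse
from pathlib import Path

import pandas as pd

from ibd_claims.codemaps import classify_claims, load_drug_code_maps, medication_hcpcs
from ibd_claims.config import StudyConfig
from ibd_claims.episodes import GapTable, build_episodes
from ibd_claims.outcomes import CpiTable, aggregate, summarize_patients
from ibd_claims.synthetic import SimTables

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--claims", type=Path, default=ROOT / "results" / "claims")
    ap.add_argument("--cohorts", type=Path, default=ROOT / "results" / "cohorts")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "utilization")
    args = ap.parse_args()

    tables = SimTables.read(args.claims)
    maps = load_drug_code_maps()
    events = classify_claims(tables.medical, tables.pharmacy, maps)
    cpi = CpiTable.from_package()
    med_set = medication_hcpcs(maps)
    gap_table = GapTable.from_code_maps(maps, grace_days=StudyConfig().grace_days)
    args.out.mkdir(parents=True, exist_ok=True)

    ir = pd.read_csv(args.cohorts / "cohort_1yr.csv", parse_dates=["index_date"])
    episodes = build_episodes(ir, events, gap_table, 365)
    summaries = summarize_patients(tables, ir, 365, cpi, med_set)
    summaries = summaries.merge(
        episodes[["person_id", "cohort", "drug", "as_treated"]], on="person_id")
    both = pd.concat(
        [summaries[summaries["as_treated"]].assign(population="as-treated"),
         summaries.assign(population="ITT")], ignore_index=True)
    agg = aggregate(both)
    agg.to_csv(args.out / "utilization_costs_1yr.csv", index=False)

    pooled = aggregate(both[both["population"] == "as-treated"],
                       ("cohort", "window")).set_index(["cohort", "window"])
    for cohort in sorted(pooled.index.get_level_values(0).unique()):
        b, f = pooled.loc[(cohort, "baseline")], pooled.loc[(cohort, "follow-up")]
        print(f"{cohort} (as-treated, n={int(b['n'])}):")
        print(f"  admissions {b['any_admission_pct']:.2f}% -> {f['any_admission_pct']:.2f}%,"
              f" ED {b['any_ed_pct']:.2f}% -> {f['any_ed_pct']:.2f}%")
        print(f"  mean costs: inpatient ${b['cost_inpatient_mean']:,.0f} -> "
              f"${f['cost_inpatient_mean']:,.0f}; pharmacy ${b['cost_pharmacy_mean']:,.0f}"
              f" -> ${f['cost_pharmacy_mean']:,.0f}; combined "
              f"${b['cost_combined_mean']:,.0f} -> ${f['cost_combined_mean']:,.0f}")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
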