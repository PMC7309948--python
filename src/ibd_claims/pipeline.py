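"""End-to-end orchestration of the claims analysis.

Chains the stages in study order — classify biologic claims, build the
cohort for the requested follow-up length, construct treatment episodes
under the permissible-gap rule, roll up windowed utilization and costs for
the as-treated and intention-to-treat (ITT) populations, and assemble the
report bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .codemaps import classify_claims, load_drug_code_maps, medication_hcpcs
from .cohort import build_cohort
from .config import StudyConfig
from .episodes import GapTable, build_episodes
from .outcomes import CpiTable, aggregate, summarize_patients
from .reporting import build_bundle
from .synthetic import SimTables


@dataclass
class AnalysisResult:
    """Outputs of one cohort analysis (one follow-up length)."""

    study: StudyConfig
    index_records: pd.DataFrame
    attrition: pd.DataFrame
    episodes: pd.DataFrame
    summaries: pd.DataFrame = field(repr=False)
    utilization_costs: pd.DataFrame = field(repr=False)
    bundle: dict = field(repr=False)


def run_analysis(
    tables: SimTables,
    study: StudyConfig,
    *,
    maps=None,
    cpi: CpiTable | None = None,
    events: pd.DataFrame | None = None,
) -> AnalysisResult:
    """Run the full pipeline on claim tables for one follow-up length."""
    if maps is None:
        maps = load_drug_code_maps()
    if cpi is None:
        cpi = CpiTable.from_package()
    if events is None:
        events = classify_claims(tables.medical, tables.pharmacy, maps)

    index_records, attrition = build_cohort(tables, events, study)
    gap_table = GapTable.from_code_maps(maps, grace_days=study.grace_days)
    episodes = build_episodes(index_records, events, gap_table, study.followup_days)

    med_set = medication_hcpcs(maps)
    summaries = summarize_patients(tables, index_records, study.followup_days, cpi, med_set)
    summaries = summaries.merge(
        episodes[["person_id", "cohort", "drug", "as_treated"]], on="person_id"
    )
    itt = summaries.assign(population="ITT")
    at = summaries[summaries["as_treated"]].assign(population="as-treated")
    both = pd.concat([at, itt], ignore_index=True)
    utilization_costs = aggregate(both, ("cohort", "drug", "population", "window"))

    bundle = build_bundle(index_records, episodes, utilization_costs, attrition)
    return AnalysisResult(
        study=study, index_records=index_records, attrition=attrition,
        episodes=episodes, summaries=summaries,
        utilization_costs=utilization_costs, bundle=bundle,
    )
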